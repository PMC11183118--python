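"""Shared read-layout constants.

A sequenced read is laid out 5'->3' as

    [4 random nt][small RNA insert][UMI, 6 nt][sRBC, 5 nt][3' adapter][...]

with the 5-nt sample barcode (sRBC) immediately adjacent to the adapter. The
simulator and the parser both import these constants so that round-trip tests
are internally consistent.
"""

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

HEAD_PAD = 4   # random nucleotides at the read start, trimmed before mapping
UMI_LEN = 6    # unique molecular identifier adjacent to the insert
SRBC_LEN = 5   # small RNA sample barcode adjacent to the adapter

DNA = "ACGT"
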