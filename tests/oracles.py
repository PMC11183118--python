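"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package implementation: the adapter
oracle is a plain scalar dynamic program, and the mapping oracle scans every
position of every contig strand for the longest common prefix.
"""
from __future__ import annotations

NEG = -(10 ** 9)


def semiglobal_oracle(read: str, adapter: str, match=1, mismatch=-1,
                      gap_open=-2, gap_extend=-1):
    """End-gap-free affine alignment of adapter vs read by plain scalar DP.

    Returns (score, start, end) with ties broken by smallest start, then
    smallest end. A gap of length g costs |gap_open| + (g-1)*|gap_extend|.
    """
    n, m = len(read), len(adapter)
    # H/E/F score matrices and parallel matrices of the best (smallest)
    # achievable start for an optimal path into each cell
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    SH = [[0] * (m + 1) for _ in range(n + 1)]
    SE = [[0] * (m + 1) for _ in range(n + 1)]
    SF = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        H[i][0] = 0
        SH[i][0] = i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # E: gap in adapter (read base consumed)
            cands = [(H[i - 1][j] + gap_open, SH[i - 1][j]),
                     (E[i - 1][j] + gap_extend, SE[i - 1][j])]
            E[i][j], SE[i][j] = max(cands, key=lambda t: (t[0], -t[1]))
            # F: gap in read (adapter base consumed)
            cands = [(H[i][j - 1] + gap_open, SH[i][j - 1]),
                     (F[i][j - 1] + gap_extend, SF[i][j - 1])]
            F[i][j], SF[i][j] = max(cands, key=lambda t: (t[0], -t[1]))
            sub = match if (read[i - 1] == adapter[j - 1]
                            and read[i - 1] != "N") else mismatch
            cands = [(H[i - 1][j - 1] + sub, SH[i - 1][j - 1]),
                     (E[i][j], SE[i][j]), (F[i][j], SF[i][j])]
            H[i][j], SH[i][j] = max(cands, key=lambda t: (t[0], -t[1]))
    best = (0, 0, 0)  # empty alignment
    for i in range(1, n + 1):  # adapter fully aligned, read suffix free
        s, st = H[i][m], SH[i][m]
        if (s, -st, -i) > (best[0], -best[1], -best[2]):
            best = (s, st, i)
    for j in range(m + 1):  # adapter suffix hangs off the read end
        s, st = H[n][j], SH[n][j]
        if (s, -st, -n) > (best[0], -best[1], -best[2]):
            best = (s, st, n)
    return best


def longest_prefix_oracle(insert: str, contigs: dict[str, str], min_prefix: int):
    """All placements of the longest exact insert prefix, by exhaustive scan.

    Returns (prefix_len, [(contig, strand, start, end), ...]); prefix_len 0
    means unmapped.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    best_len = 0
    hits = []
    for cid, seq in contigs.items():
        for strand in "+-":
            s = seq if strand == "+" else seq.translate(comp)[::-1]
            for pos in range(len(s)):
                ln = 0
                while (pos + ln < len(s) and ln < len(insert)
                       and s[pos + ln] == insert[ln]):
                    ln += 1
                if ln < min_prefix:
                    continue
                if strand == "+":
                    iv = (pos, pos + ln)
                else:
                    iv = (len(s) - pos - ln, len(s) - pos)
                if ln > best_len:
                    best_len, hits = ln, [(cid, strand, iv[0], iv[1])]
                elif ln == best_len:
                    hits.append((cid, strand, iv[0], iv[1]))
    return best_len, sorted(set(hits))
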