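"""K-mer motif enrichment around hypomethylated CpG sites.

A deterministic stand-in for EM-based motif discovery: 100-bp windows are
extracted around significant hypomethylated probes, k-mers (collapsed with
their reverse complements) are counted in foreground and background windows,
and each k-mer gets a one-sided binomial enrichment p-value against the
background rate with a Bonferroni-style e-value over the 4^k/2 canonical
k-mers. Hits are compared to the AP1 bZIP consensus TGASTCA (S = C or G).
Note this e-value is a corrected binomial p and is not numerically comparable
to E-values from EM-based motif finders.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ProbeAnnotationTable, ValidationError

AP1_CONSENSUS = "TGASTCA"
_COMP = str.maketrans("ACGTN", "TGCAN")

_ENC = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# window extraction


def extract_windows(probe_ids, manifest: ProbeAnnotationTable, genome: dict[str, str],
                    width: int = 100) -> dict[str, str]:
    """Uppercase sequence windows [pos − width/2, pos + width/2), clipped at
    chromosome ends. Windows containing N are kept (N never matches a k-mer).
    """
    probe_ids = sorted(set(probe_ids))
    probes = manifest.probes.loc[probe_ids]
    missing = sorted(set(probes["chrom"]) - set(genome))
    if missing:
        bad = [p for p in probe_ids if probes.loc[p, "chrom"] in missing]
        raise ValidationError(
            f"chromosome(s) {missing} missing from FASTA; affected probes: {bad[:5]}"
        )
    half = width // 2
    out = {}
    for pid in probe_ids:
        chrom, pos = probes.loc[pid, "chrom"], int(probes.loc[pid, "pos"])
        seq = genome[chrom]
        lo = max(pos - half, 0)
        hi = min(pos + (width - half), len(seq))
        out[pid] = seq[lo:hi].upper()
    return out


# ---------------------------------------------------------------------------
# k-mer counting


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes of all valid positions of one sequence."""
    dig = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(dig) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(dig, k)
    valid = (win >= 0).all(axis=1)
    win = win[valid]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ powers
    rc = (3 - win[:, ::-1]) @ powers
    return np.minimum(fwd, rc)


def count_canonical_kmers(windows, k: int) -> tuple[np.ndarray, int]:
    """Counts (length 4^k, indexed by canonical code) and total valid positions."""
    seqs = windows.values() if isinstance(windows, dict) else windows
    codes = [_kmer_codes(s, k) for s in seqs]
    if codes:
        allc = np.concatenate(codes)
    else:
        allc = np.empty(0, dtype=np.int64)
    counts = np.bincount(allc, minlength=4 ** k)
    return counts, int(len(allc))


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def binomial_enrichment_p(fg_count: int, fg_n: int, bg_rate: float) -> float:
    """One-sided binomial tail P(X >= fg_count) with X ~ Bin(fg_n, bg_rate)."""
    if fg_count <= 0:
        return 1.0
    return float(stats.binom.sf(fg_count - 1, fg_n, bg_rate))


def match_ap1(kmer: str, consensus: str = AP1_CONSENSUS) -> float:
    """Best ungapped alignment of the k-mer (both strands) to the AP1 consensus.

    Scored as matching positions / len(consensus); S matches C or G. Partial
    overlaps are allowed (non-overlapping consensus positions score 0).
    """
    def matches(a: str, c: str) -> bool:
        return a == c or (c == "S" and a in "CG")

    best = 0
    for strand in (kmer.upper(), revcomp(kmer.upper())):
        for off in range(-(len(consensus) - 1), len(strand)):
            score = sum(
                1
                for j, c in enumerate(consensus)
                if 0 <= off + j < len(strand) and matches(strand[off + j], c)
            )
            best = max(best, score)
    return best / len(consensus)


def kmer_enrichment(fg_windows, bg_windows, k: int = 8) -> pd.DataFrame:
    """Ranked canonical k-mer enrichment of foreground vs background windows.

    Per k-mer: one-sided binomial test of foreground occurrences against the
    background rate (pseudocount 0.5); e_value = p × 4^k/2; ranked by e_value
    ascending, ties by fg_count descending then lexicographic k-mer. Only
    k-mers observed in the foreground are reported.
    """
    seqs = list(fg_windows.values() if isinstance(fg_windows, dict) else fg_windows)
    if not seqs:
        raise ValidationError("no foreground windows")
    if min(len(s) for s in seqs) < k:
        raise ValidationError(f"k={k} exceeds the shortest window length")
    bgs = list(bg_windows.values() if isinstance(bg_windows, dict) else bg_windows)
    if not bgs:
        raise ValidationError("no background windows")

    fg_counts, fg_n = count_canonical_kmers(seqs, k)
    bg_counts, bg_n = count_canonical_kmers(bgs, k)
    observed = np.flatnonzero(fg_counts)
    n_canonical = 4 ** k / 2
    rows = []
    for code in observed:
        c = int(fg_counts[code])
        rate = (bg_counts[code] + 0.5) / (bg_n + 1.0)
        p = binomial_enrichment_p(c, fg_n, rate)
        mu = fg_n * rate
        z = (c - mu) / np.sqrt(mu * (1.0 - rate))
        kmer = decode_kmer(int(code), k)
        rows.append(
            dict(
                kmer=kmer,
                fg_count=c,
                bg_count=int(bg_counts[code]),
                enrichment_z=float(z),
                p=p,
                e_value=min(p * n_canonical, np.inf),
                ap1_similarity=match_ap1(kmer),
            )
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["e_value", "fg_count", "kmer"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# dinucleotide shuffle (Altschul–Erickson)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random permutation of a sequence preserving its dinucleotide counts.

    Eulerian-path construction: pick a random last exit edge for every vertex
    except the terminal character, verify the last-edge graph reaches the
    terminal vertex, shuffle the remaining edges, and walk.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last_char = seq[-1]
    vertices = sorted(edges)

    for _ in range(1000):
        last_edge = {}
        for v in vertices:
            if v == last_char and len(edges[v]) == 0:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        # connectivity: from every vertex, following last edges must reach last_char
        ok = True
        for v in vertices:
            if v == last_char:
                continue
            seen = {v}
            cur = v
            while cur != last_char:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian ordering")

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        order = list(rng.permutation(len(pool)))
        pool = [pool[i] for i in order]
        if v in last_edge:
            pool.append(last_edge[v])
        shuffled[v] = pool

    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffled_background(fg_windows: dict[str, str], seed: int = 0) -> dict[str, str]:
    """Seeded dinucleotide-shuffled copy of the foreground windows."""
    rng = np.random.default_rng(seed)
    return {f"shuf_{k}": dinucleotide_shuffle(s, rng) for k, s in fg_windows.items()}
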