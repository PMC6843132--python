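"""Known-motif enrichment with an exact hypergeometric tail test.

Sequences are counted under a ZOOPS rule (a sequence either contains >= 1
motif hit on either strand or it does not).  Target windows and background
sequences are pooled into one universe of N = n_target + n_background
sequences with K total motif-containing members; the enrichment p-value is
the exact hypergeometric upper tail P(X >= k) of drawing k containing
sequences among the n_target targets.  The default background is one
dinucleotide-preserving shuffle per target (Altschul-Erickson Eulerian-path
shuffle), which matches GC and dinucleotide composition without needing a
genome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .scan import ScoringMatrix, window_scores

__all__ = [
    "EnrichmentResult",
    "count_containing",
    "hypergeom_pvalue",
    "enrich",
    "dinucleotide_shuffle",
    "make_background",
    "write_enrichment_tsv",
]

#: the in-vivo analysis significance bar on the motif p-value
DEFAULT_ALPHA = 1e-30


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    target_hits: int
    target_n: int
    bg_hits: int
    bg_n: int
    p_value: float
    log10_p: float
    fold_enrichment: float
    significant: bool
    alpha: float = DEFAULT_ALPHA


def count_containing(
    sm: ScoringMatrix, seqs: Sequence[str], threshold: float
) -> int:
    """Number of sequences with >= 1 window scoring >= threshold (ZOOPS)."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    count = 0
    for seq in seqs:
        if len(seq) < sm.width:
            continue
        if window_scores(sm, seq, "+").max(initial=-np.inf) >= threshold:
            count += 1
            continue
        if window_scores(sm, seq, "-").max(initial=-np.inf) >= threshold:
            count += 1
    return count


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N, K, n).

    N sequences in the universe, K of them motif-containing, n drawn as
    targets, k containing targets observed.  Computed in log space; exact
    for small N and stable up to N ~ 1e6.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k)
    return float(np.exp(hypergeom.logsf(k - 1, N, K, n)))


def log10_hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 0.0
    return float(hypergeom.logsf(k - 1, N, K, n) / math.log(10))


def enrich(
    sm: ScoringMatrix,
    target_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    threshold: float,
    alpha: float = DEFAULT_ALPHA,
) -> EnrichmentResult:
    """ZOOPS hypergeometric enrichment of targets against a background."""
    if not target_seqs or not bg_seqs:
        raise ValueError("target and background sets must both be non-empty")
    k = count_containing(sm, target_seqs, threshold)
    bg_hits = count_containing(sm, bg_seqs, threshold)
    n, bg_n = len(target_seqs), len(bg_seqs)
    N, K = n + bg_n, k + bg_hits
    p = hypergeom_pvalue(k, n, K, N)
    log10_p = log10_hypergeom_pvalue(k, n, K, N)
    if bg_hits > 0:
        fold = (k / n) / (bg_hits / bg_n)
    else:
        fold = math.inf if k > 0 else math.nan
    return EnrichmentResult(
        motif_id=sm.source_pwm_id,
        target_hits=k,
        target_n=n,
        bg_hits=bg_hits,
        bg_n=bg_n,
        p_value=p,
        log10_p=log10_p,
        fold_enrichment=fold,
        significant=p <= alpha,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# background construction


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide multiset (Altschul-Erickson).

    The sequence is viewed as an Eulerian path in the multigraph whose edges
    are its dinucleotides; a uniform random last-edge tree rooted at the
    final base is drawn, the remaining out-edges are permuted, and the path
    is rewalked.  Sequences shorter than 3 nt are returned unchanged with a
    warning.
    """
    if len(seq) < 3:
        warnings.warn("sequence shorter than 3 nt cannot be shuffled", stacklevel=2)
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = sorted(edges)
    # draw last-edge choices until they form a tree oriented toward `last`
    # (rejection sampling; the accepted configuration is uniform over trees)
    for _ in range(10_000):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection virtually always succeeds
        raise RuntimeError("failed to sample an Eulerian last-edge tree")
    shuffled_edges: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        rest = [rest[i] for i in perm]
        if v in last_edge:
            rest.append(last_edge[v])
        shuffled_edges[v] = rest
    out = [seq[0]]
    counters = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_background(
    targets: Sequence[str],
    mode: str = "dinuc-shuffle",
    genome_fasta=None,
    n: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Build a background sequence set for enrichment testing.

    ``"dinuc-shuffle"`` returns one dinucleotide-preserving shuffle per
    target; ``"genomic-sample"`` samples ``n`` (default: len(targets))
    length-matched intervals uniformly from the genome.  Both are
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    if mode == "dinuc-shuffle":
        return [dinucleotide_shuffle(t, rng) for t in targets]
    if mode == "genomic-sample":
        if genome_fasta is None:
            raise ValueError("genomic-sample mode requires a genome FASTA")
        import pyfaidx

        fasta = (
            genome_fasta
            if isinstance(genome_fasta, pyfaidx.Fasta)
            else pyfaidx.Fasta(str(genome_fasta))
        )
        chroms = list(fasta.keys())
        sizes = np.array([len(fasta[c]) for c in chroms], dtype=float)
        probs = sizes / sizes.sum()
        n_out = n if n is not None else len(targets)
        lengths = [len(targets[i % len(targets)]) for i in range(n_out)]
        out = []
        for length in lengths:
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            hi = len(fasta[chrom]) - length
            if hi <= 0:
                raise ValueError(f"chromosome {chrom} shorter than target length")
            start = int(rng.integers(0, hi + 1))
            out.append(str(fasta[chrom][start: start + length]).upper())
        return out
    raise ValueError(f"unknown background mode {mode!r}")


def write_enrichment_tsv(result: EnrichmentResult, path) -> None:
    import pandas as pd

    pd.DataFrame([result.__dict__]).to_csv(path, sep="\t", index=False)
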