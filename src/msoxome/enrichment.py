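"""Overrepresentation analysis with one-sided Fisher's exact test and BH-FDR.

For a target protein set of size n drawn from a background of size N, a
term with K background members and k target members is scored by the
hypergeometric upper tail P(X ≥ k) — the one-sided (greater) Fisher exact
p — with fold enrichment (k/n)/(K/N). p-values across terms are adjusted
with the Benjamini–Hochberg step-up procedure. Only overrepresentation is
tested; terms with no target overlap are reported with p = 1 so that
target-vs-background tables stay alignable across universes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import AnnotationSets


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap
    n: int  # target size
    K: int  # term size in background
    N: int  # background size
    fold: float
    p: float
    q: float


def fisher_overrep(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher exact p for overrepresentation: P(X ≥ k).

    X ~ Hypergeometric(N, K, n): number of term members in a size-n draw
    from an N-protein background containing K term members.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k > min(n, K):
        raise ValueError(f"overlap k={k} exceeds min(n={n}, K={K})")
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    q_i = min over j with p_j ≥ p_i of (m · p_j / rank_j), clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def enrich(
    target_accessions: Iterable[str],
    background_accessions: Iterable[str],
    sets: AnnotationSets,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Score every annotation term against a target set and background.

    Term membership is intersected with the background before counting, so
    the test universe is exactly the proteins quantified in the experiment.
    Returns one row per term with K ≥ 1, sorted by q then p, with a
    ``significant`` flag at q ≤ q_max.
    """
    target = set(target_accessions)
    background = set(background_accessions)
    strays = target - background
    if strays:
        raise ValueError(
            f"target proteins absent from background: {sorted(strays)[:10]}"
        )
    n, N = len(target), len(background)
    rows = []
    for term in sets:
        members = sets.members(term) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & target)
        p = fisher_overrep(k, n, K, N) if n > 0 else 1.0
        fold = (k / n) / (K / N) if n > 0 else 0.0
        rows.append(
            {
                "term_id": term,
                "term_name": sets.name(term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold": fold,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= q_max
    return out.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)


def side_by_side(
    msox_results: pd.DataFrame, proteome_results: pd.DataFrame
) -> pd.DataFrame:
    """Align per-term q-values from the MSox and whole-proteome universes.

    The contrast shows which enrichments are specific to the MSox-ome
    rather than artifacts of proteome coverage.
    """
    a = msox_results.set_index("term_id")[["term_name", "q"]].rename(columns={"q": "q_msox"})
    b = proteome_results.set_index("term_id")[["q"]].rename(columns={"q": "q_proteome"})
    return a.join(b, how="outer").reset_index()
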