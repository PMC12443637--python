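"""Section–replica molecular concordance.

A nanoneedle molecular replica should reproduce the lipid profile of the
tissue it was imprinted from. Concordance is quantified by the Pearson
correlation between per-sample mean tissue spectra (replicas × sections),
the rank of each replica's own reference section within its correlation
row, and the analytic random baseline k/n those ranks are compared with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CommonRepresentation, TissueMask
from .errors import ParameterError

__all__ = [
    "CorrelationMatrix",
    "RankSummary",
    "mean_tissue_spectrum",
    "correlation_matrix",
    "rank_summary",
    "random_rank_baseline",
]


def mean_tissue_spectrum(
    representation: CommonRepresentation, mask: TissueMask
) -> np.ndarray:
    """Per-feature mean over tissue pixels (TIC-normalized scale,
    before background z-scoring)."""
    tissue = mask.pixel_flags(representation.coords)
    if not tissue.any():
        raise ParameterError("mask selects no tissue pixels")
    return representation.matrix[tissue].mean(axis=0)


@dataclass
class CorrelationMatrix:
    """Pearson r between every replica (rows) and section (columns)."""

    values: pd.DataFrame
    pairing: dict[str, str]  # replica id -> its reference section id

    def __post_init__(self) -> None:
        bad_rows = set(self.pairing) - set(self.values.index)
        bad_cols = set(self.pairing.values()) - set(self.values.columns)
        if bad_rows or bad_cols:
            raise ParameterError(
                f"pairing references unknown samples: rows {sorted(bad_rows)}, "
                f"columns {sorted(bad_cols)}"
            )


def correlation_matrix(
    sections: dict[str, np.ndarray],
    replicas: dict[str, np.ndarray],
    pairing: dict[str, str] | None = None,
    log10_transform: bool = False,
) -> CorrelationMatrix:
    """Correlate every replica mean spectrum with every section mean spectrum.

    ``sections`` and ``replicas`` map sample ids to mean tissue spectra
    on a shared feature axis. With ``log10_transform`` the correlation is
    computed on log10(x + ε) values (ε = smallest positive value × 1e-3),
    matching abundance-scatter conventions. Zero-variance vectors yield
    undefined correlations, recorded as NaN.
    """
    sec_ids = list(sections)
    rep_ids = list(replicas)
    lengths = {len(v) for v in sections.values()} | {len(v) for v in replicas.values()}
    if len(lengths) > 1:
        raise ParameterError("all mean spectra must share one feature axis")
    S = np.stack([np.asarray(sections[s], dtype=float) for s in sec_ids])
    R = np.stack([np.asarray(replicas[r], dtype=float) for r in rep_ids])
    if log10_transform:
        both = np.concatenate([S.ravel(), R.ravel()])
        positive = both[both > 0]
        eps = (positive.min() if positive.size else 1.0) * 1e-3
        S = np.log10(S + eps)
        R = np.log10(R + eps)

    Sc = S - S.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=1, keepdims=True)
    s_norm = np.linalg.norm(Sc, axis=1)
    r_norm = np.linalg.norm(Rc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Rc @ Sc.T) / np.outer(r_norm, s_norm)
    corr[:, s_norm == 0] = np.nan
    corr[r_norm == 0, :] = np.nan
    values = pd.DataFrame(corr, index=rep_ids, columns=sec_ids)
    if pairing is None:
        pairing = {r: r for r in rep_ids if r in sections}
    return CorrelationMatrix(values=values, pairing=pairing)


@dataclass
class RankSummary:
    """Rank of each replica's reference section within its correlation row."""

    ranks: pd.Series  # replica id -> competition rank (1 = best)
    n_sections: int
    excluded: list[str] = field(default_factory=list)
    ties: list[str] = field(default_factory=list)

    def frequency_top_k(self, k: int) -> float:
        if len(self.ranks) == 0:
            return float("nan")
        return float((self.ranks <= k).mean())

    @property
    def frequency_rank1(self) -> float:
        return self.frequency_top_k(1)

    @property
    def frequency_top5(self) -> float:
        return self.frequency_top_k(5)


def rank_summary(matrix: CorrelationMatrix) -> RankSummary:
    """Rank reference sections by descending correlation per replica.

    Competition ("best rank") convention for ties, with tied replicas
    flagged. Replicas with a missing (NaN) reference correlation are
    excluded and reported.
    """
    ranks = {}
    excluded, ties = [], []
    for rep, ref in matrix.pairing.items():
        row = matrix.values.loc[rep]
        r_ref = row[ref]
        if np.isnan(r_ref):
            excluded.append(rep)
            continue
        others = row.drop(labels=[ref]).to_numpy()
        better = int(np.nansum(others > r_ref))
        tied = int(np.nansum(others == r_ref))
        if tied:
            ties.append(rep)
        ranks[rep] = better + 1  # competition ranking: ties share the best rank
    return RankSummary(
        ranks=pd.Series(ranks, dtype=int),
        n_sections=matrix.values.shape[1],
        excluded=excluded,
        ties=ties,
    )


def random_rank_baseline(
    n_candidates: int,
    top_k: int,
    monte_carlo_draws: int = 0,
    seed: int = 0,
) -> float | tuple[float, float]:
    """Probability that a uniformly random ranking lands in the top k.

    Analytically ``top_k / n_candidates``. With ``monte_carlo_draws`` > 0
    also returns the Monte-Carlo estimate over that many uniform random
    rank draws, for verification.
    """
    if not 1 <= top_k <= n_candidates:
        raise ParameterError("top_k must lie in [1, n_candidates]")
    exact = top_k / n_candidates
    if monte_carlo_draws <= 0:
        return exact
    rng = np.random.default_rng(seed)
    draws = rng.integers(1, n_candidates + 1, size=monte_carlo_draws)
    return exact, float((draws <= top_k).mean())
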