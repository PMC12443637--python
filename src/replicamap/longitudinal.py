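"""Longitudinal treatment-response statistics.

The design: live tumour-bearing brain slices are sampled at day 0 and
day 5, with half the slices treated (arm T1, e.g. temozolomide) from
day 3 and half left as controls (T0). Per lipid species, the abundance
is the mean over tumour-classified pixels (TIC-normalized scale), one
value per (brain, timepoint, arm) cell.

Two statistics are computed per species:

* **time effect** (untreated arm only): ANOVA on a univariate linear
  regression of abundance on time; significant when P < 0.01 and
  |log2(D5T0/D0T0)| > 2.
* **treatment effect**: the drift-corrected difference
  ΔT = ΔT1 − ΔT0 with ΔTa = [D5Ta] − [D0Ta], computed per brain and
  averaged, then standardized across the species universe (z(ΔT));
  significance requires the ANOVA treatment term of the linear model
  ``abundance ~ time + treatment`` at P < 0.01 together with
  |z(ΔT)| > 0.5. A negative ΔT is a net decrease attributable to
  treatment, net of the shared temporal drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CommonRepresentation
from .errors import ParameterError
from .regions import RegionLabels

__all__ = [
    "tumour_abundance",
    "build_series",
    "time_effect",
    "delta_t",
    "treatment_effect",
    "TimeEffectResult",
    "DeltaTResult",
]

SERIES_COLUMNS = ["species_mz", "brain_id", "timepoint", "arm", "abundance"]
VARIANCE_FLOOR = 1e-12


def tumour_abundance(
    representation: CommonRepresentation,
    labels: RegionLabels,
    region: str | int = "T",
) -> pd.DataFrame:
    """Per-species mean abundance over a region's pixels.

    Species that are zero across every pixel of the region are flagged
    undetectable.
    """
    rows = labels.pixels_of(region)
    if rows.size == 0:
        raise ParameterError(f"region {region!r} has no pixels")
    sub = representation.matrix[rows]
    mean = sub.mean(axis=0)
    return pd.DataFrame(
        {
            "species_mz": representation.feature_mz,
            "abundance": mean,
            "undetectable": (sub != 0).sum(axis=0) == 0,
        }
    )


def build_series(
    cells: dict[tuple[str, str, str], pd.DataFrame]
) -> pd.DataFrame:
    """Stack per-cell abundance tables into a long series.

    ``cells`` maps (brain_id, timepoint, arm) to the output of
    :func:`tumour_abundance`.
    """
    frames = []
    for (brain, timepoint, arm), table in cells.items():
        f = table[["species_mz", "abundance"]].copy()
        f["brain_id"], f["timepoint"], f["arm"] = brain, timepoint, arm
        frames.append(f)
    return pd.concat(frames, ignore_index=True)[SERIES_COLUMNS]


def _pseudocount(series: pd.DataFrame) -> float:
    positive = series.loc[series["abundance"] > 0, "abundance"]
    return (positive.min() if len(positive) else 1.0) * 1e-3


@dataclass
class TimeEffectResult:
    """Per-species temporal drift calls in the untreated arm."""

    table: pd.DataFrame  # species_mz, log2_ratio, p_time, significant, undetectable_d5
    p_threshold: float
    lfc_threshold: float

    @property
    def significant_mz(self) -> np.ndarray:
        return self.table.loc[self.table.significant, "species_mz"].to_numpy()


def _anova_regression_p(y: np.ndarray, x: np.ndarray) -> float:
    """F-test p of a univariate linear regression (ANOVA on the model).

    A variance floor keeps zero-residual designs finite (they come out
    overwhelmingly significant, as they should).
    """
    n = y.size
    if n < 3 or np.ptp(x) == 0:
        return 1.0
    xc = x - x.mean()
    yc = y - y.mean()
    beta = (xc @ yc) / (xc @ xc)
    fitted = beta * xc
    ssr = float(fitted @ fitted)
    sse = float((yc - fitted) @ (yc - fitted))
    if ssr == 0.0:
        return 1.0
    f = ssr / (max(sse, VARIANCE_FLOOR) / (n - 2))
    return float(stats.f.sf(f, 1, n - 2))


def time_effect(
    series: pd.DataFrame,
    p_threshold: float = 0.01,
    lfc_threshold: float = 2.0,
) -> TimeEffectResult:
    """Temporal change per species in untreated brains (D0T0 vs D5T0).

    Per species, abundance is regressed on time (D0 = 0, D5 = 1) with
    each brain an observation; the ANOVA F-test p and the pseudocounted
    log2 ratio of timepoint means decide significance. Species with no
    D0 signal in any brain are excluded (counted); species undetectable
    at D5 are reported in their own category.
    """
    t0 = series[series["arm"] == "T0"]
    for tp in ("D0", "D5"):
        n = t0.loc[t0["timepoint"] == tp, "brain_id"].nunique()
        if n < 2:
            raise ParameterError(f"need >= 2 brains at {tp}, found {n}")
    eps = _pseudocount(t0)
    rows = []
    n_excluded = 0
    pivot = t0.pivot_table(
        index="species_mz", columns=["timepoint", "brain_id"], values="abundance"
    )
    d0 = pivot["D0"]
    d5 = pivot["D5"]
    for mz in pivot.index:
        a0 = d0.loc[mz].dropna().to_numpy()
        a5 = d5.loc[mz].dropna().to_numpy()
        if a0.size == 0 or np.all(a0 == 0):
            n_excluded += 1
            continue
        undetectable_d5 = a5.size == 0 or np.all(a5 == 0)
        y = np.concatenate([a0, a5])
        x = np.concatenate([np.zeros(a0.size), np.ones(a5.size)])
        p = _anova_regression_p(y, x)
        log2_ratio = float(np.log2((a5.mean() + eps) / (a0.mean() + eps))) if a5.size else np.nan
        significant = (
            (not undetectable_d5)
            and p < p_threshold
            and abs(log2_ratio) > lfc_threshold
        )
        rows.append(
            {
                "species_mz": mz,
                "log2_ratio": log2_ratio,
                "p_time": p,
                "significant": significant,
                "undetectable_d5": undetectable_d5,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_excluded_no_d0"] = n_excluded
    return TimeEffectResult(table, p_threshold, lfc_threshold)


@dataclass
class DeltaTResult:
    """Per-species treatment-effect table.

    Columns: delta_t0, delta_t1, delta_t (= delta_t1 − delta_t0,
    averaged over brains), z_delta (standardized across the species
    universe), n_brains, and — after :func:`treatment_effect` —
    p_treatment and significant.
    """

    table: pd.DataFrame
    mode: str = "delta_only"

    @property
    def significant_mz(self) -> np.ndarray:
        if "significant" not in self.table:
            raise ParameterError("run treatment_effect to obtain significance calls")
        return self.table.loc[self.table.significant, "species_mz"].to_numpy()


def delta_t(series: pd.DataFrame) -> DeltaTResult:
    """The ΔT statistic per species.

    ΔT0 = [D5T0] − [D0T0] and ΔT1 = [D5T1] − [D0T1] are computed per
    brain (each tissue slice is a separate sample) and ΔT = ΔT1 − ΔT0
    averaged across brains. Brains missing any of the four cells for a
    species are excluded for that species and counted. z(ΔT)
    standardizes ΔT over the species universe: species detected (> 0)
    at D0 in both arms in every brain.
    """
    pivot = series.pivot_table(
        index="species_mz",
        columns=["timepoint", "arm", "brain_id"],
        values="abundance",
    )
    required = [("D0", "T0"), ("D5", "T0"), ("D0", "T1"), ("D5", "T1")]
    for key in required:
        if key not in {(t, a) for t, a, _b in pivot.columns}:
            raise ParameterError(f"series lacks cell {key}")
    brains = sorted({b for _t, _a, b in pivot.columns})
    rows = []
    for mz in pivot.index:
        dt0s, dt1s = [], []
        n_excl = 0
        for b in brains:
            try:
                cell = {
                    (t, a): pivot.loc[mz, (t, a, b)] for t, a in required
                }
            except KeyError:
                n_excl += 1
                continue
            if any(pd.isna(v) for v in cell.values()):
                n_excl += 1
                continue
            dt0s.append(cell[("D5", "T0")] - cell[("D0", "T0")])
            dt1s.append(cell[("D5", "T1")] - cell[("D0", "T1")])
        if not dt0s:
            continue
        dt0 = float(np.mean(dt0s))
        dt1 = float(np.mean(dt1s))
        # universe membership: detected at D0 in both arms in every brain
        d0_t0 = pivot.loc[mz, ("D0", "T0")].to_numpy()
        d0_t1 = pivot.loc[mz, ("D0", "T1")].to_numpy()
        in_universe = (
            not np.any(pd.isna(d0_t0))
            and not np.any(pd.isna(d0_t1))
            and np.all(d0_t0 > 0)
            and np.all(d0_t1 > 0)
        )
        rows.append(
            {
                "species_mz": mz,
                "delta_t0": dt0,
                "delta_t1": dt1,
                "delta_t": dt1 - dt0,
                "n_brains": len(dt0s),
                "n_brains_excluded": n_excl,
                "in_universe": in_universe,
            }
        )
    table = pd.DataFrame(rows)
    universe = table["in_universe"].to_numpy()
    z = np.full(len(table), np.nan)
    if universe.sum() >= 2:
        vals = table.loc[universe, "delta_t"].to_numpy()
        sd = vals.std(ddof=0)
        z[universe] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    table["z_delta"] = z
    return DeltaTResult(table)


def _anova_p_for_term(y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray) -> float:
    """Partial F-test p for the terms present in X_full but not X_reduced."""

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), np.linalg.matrix_rank(X)

    rss_full, rank_full = rss(X_full)
    rss_red, rank_red = rss(X_reduced)
    df_num = rank_full - rank_red
    df_den = y.size - rank_full
    if df_num < 1 or df_den < 1:
        return np.nan
    num = max(rss_red - rss_full, 0.0) / df_num
    den = max(rss_full, VARIANCE_FLOOR) / df_den
    if num == 0.0:
        return 1.0
    return float(stats.f.sf(num / den, df_num, df_den))


def treatment_effect(
    series: pd.DataFrame,
    mode: str = "interaction",
    p_threshold: float = 0.01,
    z_threshold: float = 0.5,
) -> DeltaTResult:
    """Treatment-responsive species calls.

    Per species, the ANOVA p of the treatment-associated term in a
    linear model on the (brain × timepoint × arm) abundances:

    * ``interaction`` (default): ``abundance ~ time + treatment +
      time:treatment``, testing the interaction — the term that carries
      a treatment effect which only emerges between the timepoints
      (treatment starts after day 0, so day-0 arms are exchangeable);
    * ``paired``: the interaction model plus brain (slice) indicator
      terms, absorbing slice-to-slice offsets;
    * ``base``: ``abundance ~ time + treatment``, testing the treatment
      main effect. Note that with a day-5-only effect the main-effect
      partial F saturates at the design's degrees of freedom (F ≤ 9 for
      three brains), so this mode cannot reach P < 0.01 at that scale
      regardless of effect size; it is kept for model comparison.

    A species is significant when ``p < p_threshold`` and
    ``|z(ΔT)| > z_threshold``. Rank-deficient designs are flagged and
    excluded from the calls.
    """
    if mode not in ("base", "interaction", "paired"):
        raise ParameterError(f"unknown mode {mode!r}")
    result = delta_t(series)
    table = result.table
    long = series.dropna(subset=["abundance"])
    n_brains = long["brain_id"].nunique()
    if n_brains < 2:
        raise ParameterError("need >= 2 brains")

    p_vals, flags = [], []
    brains = sorted(long["brain_id"].unique())
    for mz in table["species_mz"]:
        sub = long[long["species_mz"] == mz]
        y = sub["abundance"].to_numpy(dtype=float)
        t = (sub["timepoint"] == "D5").to_numpy(dtype=float)
        g = (sub["arm"] == "T1").to_numpy(dtype=float)
        ones = np.ones_like(t)
        base_cols = [ones, t, g]
        reduced_cols = [ones, t]
        if mode == "interaction":
            base_cols = [ones, t, g, t * g]
            reduced_cols = [ones, t, g]
        elif mode == "paired":
            dummies = [
                (sub["brain_id"] == b).to_numpy(dtype=float) for b in brains[1:]
            ]
            base_cols = [ones, t, g, t * g, *dummies]
            reduced_cols = [ones, t, g, *dummies]
        X_full = np.column_stack(base_cols)
        X_red = np.column_stack(reduced_cols)
        rank_deficient = np.linalg.matrix_rank(X_full) < X_full.shape[1]
        p = _anova_p_for_term(y, X_full, X_red)
        p_vals.append(p)
        flags.append(rank_deficient or np.isnan(p))
    table = table.copy()
    table["p_treatment"] = p_vals
    table["rank_deficient"] = flags
    table["significant"] = (
        (table["p_treatment"] < p_threshold)
        & (table["z_delta"].abs() > z_threshold)
        & ~table["rank_deficient"]
        & table["in_universe"]
    )
    return DeltaTResult(table, mode=mode)
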