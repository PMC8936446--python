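"""Bulk CPD quantitation from T4 endonuclease V alkaline-gel densitometry.

A lane digested with T4 endonuclease V (which nicks DNA at CPDs) runs as a
fragment-length distribution; comparing its number-average fragment length
``Ln`` with that of the undigested control lane yields the lesion density:

    CPDs/kb = 1/Ln(+enzyme) - 1/Ln(-enzyme)

because every cut adds one molecule end, and 1/Ln counts molecule ends per
unit mass.  Percent repair at time t normalises the lesion density to the
0 hr sample: 100 x (1 - D(t)/D(0)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GelLane:
    """Densitometry profile of one gel lane plus its ladder calibration.

    ``profile`` is (migration distance, intensity) pairs with strictly
    increasing migration; ``ladder`` is (migration distance, fragment length
    in bp) anchor pairs.  Intensity is stain signal, proportional to DNA mass.
    """

    sample_id: str
    enzyme: str  # "plus" (T4 endoV digested) or "minus" (no-enzyme control)
    profile: np.ndarray  # shape (n, 2): migration, intensity
    ladder: np.ndarray   # shape (m, 2): migration, length_bp

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        self.ladder = np.asarray(self.ladder, dtype=float)
        if self.ladder.shape[0] < 2:
            raise ValueError("ladder needs at least 2 anchor points")
        if np.any(self.profile[:, 1] < 0):
            raise ValueError("intensities must be >= 0")
        if np.any(np.diff(self.profile[:, 0]) <= 0):
            raise ValueError("migration distances must be strictly increasing")


@dataclass
class BulkRepairCurve:
    """Per-timepoint lesion densities and percent repair with replicates.

    ``data`` has one row per (timepoint, replicate) with columns
    ``cpds_per_kb``, ``fraction_remaining``, ``percent_repair``.
    """

    data: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean and SEM (sd/sqrt(n)) of percent repair per timepoint."""
        g = self.data.groupby("timepoint")["percent_repair"]
        out = pd.DataFrame({
            "mean_percent_repair": g.mean(),
            "sem_percent_repair": g.std(ddof=1) / np.sqrt(g.count()),
            "n_replicates": g.count(),
        })
        out["sem_percent_repair"] = out["sem_percent_repair"].fillna(0.0)
        fr = self.data.groupby("timepoint")["fraction_remaining"].mean()
        out["mean_fraction_remaining"] = fr
        return out.reset_index()

    def fraction_remaining(self, timepoint: float) -> float:
        """Mean fraction of lesions remaining at a timepoint (for scaling
        sequencing-based repair fractions)."""
        sub = self.data[self.data["timepoint"] == timepoint]
        if len(sub) == 0:
            raise KeyError(f"no timepoint {timepoint} in curve")
        return float(sub["fraction_remaining"].mean())


def calibrate_lengths(lane: GelLane) -> np.ndarray:
    """Convert a lane profile from migration distance to fragment length.

    Electrophoretic migration is close to linear in log(length), so anchors
    are interpolated log-linearly; profile points outside the ladder range are
    extrapolated with the end-segment slope (with a warning).

    Returns an array of shape (n, 2): (fragment length in kb, intensity).
    """
    mig = lane.ladder[:, 0]
    length_bp = lane.ladder[:, 1]
    order = np.argsort(mig)
    mig, length_bp = mig[order], length_bp[order]
    if np.any(np.diff(mig) <= 0) or np.any(np.diff(length_bp) >= 0):
        raise ValueError("ladder must be strictly monotone "
                         "(increasing migration, decreasing length)")
    x = lane.profile[:, 0]
    logL = np.interp(x, mig, np.log10(length_bp))
    below, above = x < mig[0], x > mig[-1]
    if below.any() or above.any():
        warnings.warn("profile extends beyond ladder range; extrapolating "
                      "log-linearly", stacklevel=2)
        slope_lo = (np.log10(length_bp[1]) - np.log10(length_bp[0])) / (mig[1] - mig[0])
        slope_hi = (np.log10(length_bp[-1]) - np.log10(length_bp[-2])) / (mig[-1] - mig[-2])
        logL[below] = np.log10(length_bp[0]) + slope_lo * (x[below] - mig[0])
        logL[above] = np.log10(length_bp[-1]) + slope_hi * (x[above] - mig[-1])
    length_kb = 10.0 ** logL / 1000.0
    return np.column_stack([length_kb, lane.profile[:, 1]])


def number_average_length(length_profile: np.ndarray) -> float:
    """Number-average fragment length Ln (kb) from a (length, intensity)
    profile.

    Stain intensity is proportional to mass, so the molecule count in a bin is
    I/L and Ln = sum(I) / sum(I/L).
    """
    profile = np.asarray(length_profile, dtype=float)
    L, I = profile[:, 0], profile[:, 1]
    keep = I > 0
    L, I = L[keep], I[keep]
    if I.sum() <= 0:
        raise ValueError("total intensity must be > 0")
    if np.any(L <= 0):
        raise ValueError("fragment lengths must be > 0")
    return float(I.sum() / (I / L).sum())


def lesions_per_kb(ln_plus_enzyme: float, ln_minus_enzyme: float) -> float:
    """Lesion density from digested and no-enzyme number-average lengths (kb).

    Negative estimates (digested lane running *longer* than the control) are
    floored to 0 with a warning.
    """
    if ln_plus_enzyme <= 0 or ln_minus_enzyme <= 0:
        raise ValueError("number-average lengths must be > 0")
    d = 1.0 / ln_plus_enzyme - 1.0 / ln_minus_enzyme
    if d < 0:
        warnings.warn(f"negative lesion estimate ({d:.4g}/kb) floored to 0",
                      stacklevel=2)
        return 0.0
    return float(d)


def percent_repair(cpds_per_kb: Mapping[float, Sequence[float]]) -> BulkRepairCurve:
    """Build a repair curve from raw CPDs/kb values per timepoint.

    ``cpds_per_kb`` maps timepoint (hours) to per-replicate lesion densities;
    replicate i at time t is normalised to replicate i at 0 hr (replicates are
    matched experiments).  If replicate counts differ, each timepoint is
    normalised to the mean 0 hr density instead.
    """
    if 0 not in cpds_per_kb and 0.0 not in cpds_per_kb:
        raise ValueError("0 hr timepoint is required")
    d0 = np.asarray(cpds_per_kb[0] if 0 in cpds_per_kb else cpds_per_kb[0.0],
                    dtype=float)
    if np.any(d0 <= 0):
        raise ValueError("0 hr CPDs/kb must be > 0")
    matched = all(len(v) == len(d0) for v in cpds_per_kb.values())
    rows = []
    for t in sorted(cpds_per_kb):
        vals = np.asarray(cpds_per_kb[t], dtype=float)
        denom = d0 if matched else np.full(len(vals), d0.mean())
        for i, (d, dd) in enumerate(zip(vals, denom)):
            frac = d / dd
            rows.append({"timepoint": float(t), "replicate": i,
                         "cpds_per_kb": d, "fraction_remaining": frac,
                         "percent_repair": 100.0 * (1.0 - frac)})
    return BulkRepairCurve(pd.DataFrame(rows))


def curve_from_fractions(fractions: Mapping[float, Sequence[float]],
                         cpds_per_kb_0hr: float = 1.0) -> BulkRepairCurve:
    """Build a curve directly from fraction-remaining replicates (e.g. from a
    simulator or a pre-quantified gel)."""
    rows = []
    for t in sorted(fractions):
        for i, f in enumerate(fractions[t]):
            rows.append({"timepoint": float(t), "replicate": i,
                         "cpds_per_kb": cpds_per_kb_0hr * f,
                         "fraction_remaining": float(f),
                         "percent_repair": 100.0 * (1.0 - f)})
    return BulkRepairCurve(pd.DataFrame(rows))


def repair_ttest(group_a: Sequence[float], group_b: Sequence[float],
                 welch: bool = True) -> dict:
    """Two-sided two-sample t-test on replicate percent-repair values.

    Welch (unequal-variance) by default; ``welch=False`` gives the pooled
    Student variant.  Two constant, equal groups return t=0, p=1 by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(a.size + b.size - 2), "p": 1.0}
        return {"t": np.inf if a.mean() > b.mean() else -np.inf,
                "df": float(a.size + b.size - 2), "p": 0.0}
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = getattr(res, "df", None)
    if df is None:  # older scipy
        df = a.size + b.size - 2
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}
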