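"""Strand-specific repair metrics.

The central quantity is the *fraction of CPDs remaining*: lesion counts at a
repair timepoint divided by the matched 0 hr counts over a region, computed
separately for the transcribed strand (TS) and non-transcribed strand (NTS)
of each gene.  Because absolute CPD-seq library yields vary, two rescaling
strategies are provided:

* **gel scaling** — multiply every regional fraction by a factor chosen so
  the genome-wide fraction matches the bulk fraction remaining measured on
  an alkaline gel;
* **intergenic-median scaling** — for a test-vs-reference comparison, divide
  the test profile by the median of the flank-bin (intergenic) test/reference
  ratios, so that the median intergenic ratio becomes 1.

The metagene layout follows the 12-bin convention: 3 upstream flank bins of
167 bp flush to the TSS, 6 equal body sextiles between TSS and TES, and 3
downstream flank bins of 167 bp flush to the TES, all in transcription
orientation.  Repair asymmetry per bin is log2(fraction TS / fraction NTS);
values below zero mean faster TS repair, the signature of TC-NER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, LesionTrack

logger = logging.getLogger(__name__)

ROLES = ("TS", "NTS")
N_BINS = 12
FLANK_IDX = (0, 1, 2, 9, 10, 11)
BODY_IDX = (3, 4, 5, 6, 7, 8)


# ---------------------------------------------------------------------------
# bin geometry
# ---------------------------------------------------------------------------

def gene_bins(gene: GeneModel, flank_bin_bp: int = 167,
              n_body_bins: int = 6, n_flank_bins: int = 3,
              ) -> list[tuple[int, int]]:
    """Genomic [start, end) intervals of the metagene bins, in transcription
    order: upstream flank (furthest first), body sextiles, downstream flank.

    Body lengths not divisible by ``n_body_bins`` put the extra base pairs
    one at a time into the first bins (in transcription orientation).  Flank
    bins sit flush against the TSS/TES.
    """
    L = gene.body_length
    base, rem = divmod(L, n_body_bins)
    sizes = [base + 1] * rem + [base] * (n_body_bins - rem)
    cum = np.concatenate([[0], np.cumsum(sizes)])
    bins: list[tuple[int, int]] = []
    if gene.strand == "+":
        for i in range(n_flank_bins):
            bins.append((gene.tss - (n_flank_bins - i) * flank_bin_bp,
                         gene.tss - (n_flank_bins - 1 - i) * flank_bin_bp))
        for j in range(n_body_bins):
            bins.append((gene.tss + int(cum[j]), gene.tss + int(cum[j + 1])))
        for i in range(n_flank_bins):
            bins.append((gene.tes + i * flank_bin_bp,
                         gene.tes + (i + 1) * flank_bin_bp))
    else:
        up_edge = gene.tss + 1    # exclusive genomic end of the body
        for i in range(n_flank_bins):
            bins.append((up_edge + (n_flank_bins - 1 - i) * flank_bin_bp,
                         up_edge + (n_flank_bins - i) * flank_bin_bp))
        for j in range(n_body_bins):
            bins.append((up_edge - int(cum[j + 1]), up_edge - int(cum[j])))
        down_edge = gene.tes + 1  # exclusive genomic end of the downstream flank
        for i in range(n_flank_bins):
            bins.append((down_edge - (i + 1) * flank_bin_bp,
                         down_edge - i * flank_bin_bp))
    return bins


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BinProfile:
    """Pooled per-bin lesion counts and fractions remaining for TS and NTS.

    ``fractions`` are the scaled values (raw ratio x ``scale_factor``); bins
    whose pooled 0 hr count is zero are NaN (undefined), never 0.
    """

    counts_0: dict[str, np.ndarray]
    counts_t: dict[str, np.ndarray]
    n_genes: int
    scale_factor: float = 1.0
    per_gene_fractions: Optional[dict[str, np.ndarray]] = None

    @property
    def raw_fractions(self) -> dict[str, np.ndarray]:
        out = {}
        for role in ROLES:
            if self.per_gene_fractions is not None:
                out[role] = self.per_gene_fractions[role]
                continue
            c0 = self.counts_0[role].astype(float)
            ct = self.counts_t[role].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(c0 > 0, ct / np.where(c0 > 0, c0, 1.0), np.nan)
            out[role] = f
        return out

    @property
    def fractions(self) -> dict[str, np.ndarray]:
        return {r: f * self.scale_factor for r, f in self.raw_fractions.items()}

    def rescaled(self, factor: float) -> "BinProfile":
        return BinProfile(counts_0=self.counts_0, counts_t=self.counts_t,
                          n_genes=self.n_genes,
                          scale_factor=self.scale_factor * factor,
                          per_gene_fractions=self.per_gene_fractions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        fr, raw = self.fractions, self.raw_fractions
        for role in ROLES:
            for i in range(N_BINS):
                rows.append({
                    "bin": i + 1, "strand_role": role,
                    "region": ("upstream" if i < 3 else
                               "body" if i < 9 else "downstream"),
                    "counts_0": int(self.counts_0[role][i]),
                    "counts_t": int(self.counts_t[role][i]),
                    "fraction": raw[role][i],
                    "scaled_fraction": fr[role][i],
                })
        return pd.DataFrame(rows)


@dataclass
class SingleNtProfile:
    """TSS-aligned per-nucleotide fractions remaining with a dyad overlay."""

    offsets: np.ndarray
    fractions: dict[str, np.ndarray]
    counts_0: dict[str, np.ndarray]
    counts_t: dict[str, np.ndarray]
    dyad_coverage: Optional[np.ndarray]
    n_genes: int
    smooth: int
    scale_factor: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets})
        for role in ROLES:
            df[f"fraction_{role}"] = self.fractions[role]
            df[f"counts_0_{role}"] = self.counts_0[role]
            df[f"counts_t_{role}"] = self.counts_t[role]
        if self.dyad_coverage is not None:
            df["dyad_coverage"] = self.dyad_coverage
        return df


@dataclass
class GeneRepairMatrix:
    """Gene x (bin, strand-role) fractions remaining (or differences).

    ``data`` columns are TS_bin01..TS_bin12, NTS_bin01..NTS_bin12, indexed by
    gene id in display order.
    """

    data: pd.DataFrame
    order_key: str
    is_difference: bool = False

    def to_cdt(self, path) -> None:
        """Clustered-data-table text for tree-view heatmap viewers."""
        with open(path, "w") as fh:
            cols = "\t".join(self.data.columns)
            fh.write(f"GID\tNAME\tGWEIGHT\t{cols}\n")
            fh.write("EWEIGHT\t\t\t" + "\t".join(["1"] * len(self.data.columns)) + "\n")
            for i, (gid, row) in enumerate(self.data.iterrows()):
                vals = "\t".join("" if pd.isna(v) else f"{v:.6g}" for v in row)
                fh.write(f"GENE{i}X\t{gid}\t1\t{vals}\n")


# ---------------------------------------------------------------------------
# fractions and scaling
# ---------------------------------------------------------------------------

def fraction_remaining(track_t: LesionTrack, track_0: LesionTrack,
                       regions: Sequence[tuple[str, str, int, int]],
                       ) -> np.ndarray:
    """Raw fraction of CPDs remaining per strand-qualified region
    (chrom, strand, start, end); NaN where the 0 hr count is zero."""
    chroms_0 = set(track_0.chroms())
    missing = {r[0] for r in regions} - chroms_0
    if missing:
        raise ValueError(f"regions reference chroms absent from the 0 hr "
                         f"track: {sorted(missing)}")
    out = np.empty(len(regions))
    for i, (chrom, strand, start, end) in enumerate(regions):
        c0 = track_0.region_sum(chrom, strand, start, end)
        ct = track_t.region_sum(chrom, strand, start, end)
        out[i] = ct / c0 if c0 > 0 else np.nan
    return out


def gel_scale_factor(track_t: LesionTrack, track_0: LesionTrack,
                     gel_fraction_remaining: float) -> float:
    """Factor s such that s x (genome-wide raw fraction) equals the bulk
    alkaline-gel fraction remaining."""
    if not 0.0 < gel_fraction_remaining <= 1.0:
        raise ValueError("gel fraction remaining must be in (0, 1]")
    total_0 = track_0.total_count
    if total_0 == 0:
        raise ValueError("0 hr track has no lesions; cannot scale")
    raw = track_t.total_count / total_0
    return gel_fraction_remaining / raw


def gel_scale(raw, track_t: LesionTrack, track_0: LesionTrack,
              gel_fraction_remaining: float):
    """Scale raw fractions (array or BinProfile) so the genome-wide fraction
    matches the gel measurement.  Returns (scaled, scale_factor)."""
    s = gel_scale_factor(track_t, track_0, gel_fraction_remaining)
    if isinstance(raw, BinProfile):
        return raw.rescaled(s), s
    return np.asarray(raw, dtype=float) * s, s


def intergenic_median_scale(profile_test: BinProfile, profile_ref: BinProfile,
                            ) -> tuple[BinProfile, float]:
    """Divide the test profile by the median flank-bin test/reference ratio.

    The 12 ratios (6 flank bins x TS/NTS) must all be defined and positive in
    the reference; after scaling, the median ratio is 1.
    """
    ft, fr = profile_test.fractions, profile_ref.fractions
    ratios, bad = [], []
    for role in ROLES:
        for i in FLANK_IDX:
            r_ref, r_test = fr[role][i], ft[role][i]
            if not np.isfinite(r_ref) or r_ref <= 0 or not np.isfinite(r_test):
                bad.append(f"{role} bin {i + 1}")
            else:
                ratios.append(r_test / r_ref)
    if bad:
        raise ValueError(f"undefined/zero flank bins: {', '.join(bad)}")
    m = float(np.median(ratios))
    return profile_test.rescaled(1.0 / m), m


# ---------------------------------------------------------------------------
# metagene bin profile and asymmetry
# ---------------------------------------------------------------------------

def _filter_genes(genes: Sequence[GeneModel], n_body_bins: int,
                  denylist: Sequence[str]) -> list[GeneModel]:
    kept = []
    for g in genes:
        if g.chrom in denylist:
            logger.debug("excluding %s: chrom %s on denylist", g.gene_id, g.chrom)
            continue
        if g.body_length < n_body_bins:
            logger.debug("excluding %s: body %d bp < %d bins",
                         g.gene_id, g.body_length, n_body_bins)
            continue
        kept.append(g)
    if len(kept) < len(genes):
        logger.info("bin profile: %d of %d genes retained",
                    len(kept), len(genes))
    return kept


def bin_profile(track_t: LesionTrack, track_0: LesionTrack,
                genes: Sequence[GeneModel], flank_bin_bp: int = 167,
                n_body_bins: int = 6, n_flank_bins: int = 3,
                per_gene_mean: bool = False,
                denylist: Sequence[str] = ()) -> BinProfile:
    """Pooled 12-bin fraction-of-CPDs-remaining profile for TS and NTS.

    Default aggregation pools lesion counts across genes per bin and takes a
    single ratio (robust to sparse per-gene counts); ``per_gene_mean``
    instead averages the per-gene bin fractions over genes where defined.
    No scaling is applied here; compose with :func:`gel_scale` or
    :func:`intergenic_median_scale`.
    """
    kept = _filter_genes(genes, n_body_bins, denylist)
    if not kept:
        raise ValueError("no genes pass the bin-profile filters")
    counts_0 = {r: np.zeros(N_BINS, dtype=np.int64) for r in ROLES}
    counts_t = {r: np.zeros(N_BINS, dtype=np.int64) for r in ROLES}
    pg: dict[str, list[np.ndarray]] = {r: [] for r in ROLES}
    for g in kept:
        bins = gene_bins(g, flank_bin_bp, n_body_bins, n_flank_bins)
        for role, strand in (("TS", g.ts_strand), ("NTS", g.nts_strand)):
            c0 = np.array([track_0.region_sum(g.chrom, strand, s, e)
                           for s, e in bins], dtype=np.int64)
            ct = np.array([track_t.region_sum(g.chrom, strand, s, e)
                           for s, e in bins], dtype=np.int64)
            counts_0[role] += c0
            counts_t[role] += ct
            if per_gene_mean:
                with np.errstate(divide="ignore", invalid="ignore"):
                    pg[role].append(np.where(c0 > 0, ct / np.where(c0 > 0, c0, 1),
                                             np.nan))
    per_gene_fractions = None
    if per_gene_mean:
        with np.errstate(invalid="ignore"):
            per_gene_fractions = {r: np.nanmean(np.vstack(pg[r]), axis=0)
                                  for r in ROLES}
    return BinProfile(counts_0=counts_0, counts_t=counts_t,
                      n_genes=len(kept),
                      per_gene_fractions=per_gene_fractions)


def asymmetry(profile: BinProfile) -> np.ndarray:
    """Per-bin log2(fraction TS / fraction NTS); NaN where either side is
    undefined or non-positive.  Invariant under any common scale factor."""
    fr = profile.fractions
    ts, nts = fr["TS"], fr["NTS"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.isfinite(ts) & np.isfinite(nts) & (ts > 0) & (nts > 0),
                       np.log2(np.where(ts > 0, ts, 1) /
                               np.where(nts > 0, nts, 1)),
                       np.nan)
    return out


def asymmetry_frame(profile: BinProfile) -> pd.DataFrame:
    a = asymmetry(profile)
    return pd.DataFrame({"bin": np.arange(1, N_BINS + 1),
                         "region": ["upstream"] * 3 + ["body"] * 6 + ["downstream"] * 3,
                         "log2_ts_over_nts": a})


# ---------------------------------------------------------------------------
# single-nucleotide TSS profile
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    if width % 2 == 0:
        raise ValueError("smoothing width must be odd")
    kernel = np.ones(width)
    num = np.convolve(x.astype(float), kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def tss_profile(track_t: LesionTrack, track_0: LesionTrack,
                genes: Sequence[GeneModel],
                chrom_lengths: Mapping[str, int],
                window: tuple[int, int] = (-200, 1000), smooth: int = 11,
                dyads: Optional[Mapping[str, np.ndarray]] = None,
                scale_factor: float = 1.0) -> SingleNtProfile:
    """Fraction remaining per nucleotide offset from the TSS, pooled across
    genes in transcription orientation (minus-strand genes mirrored).

    Counts are pooled per offset, smoothed with a centered moving average of
    odd width (the same window on the 0 hr and timepoint counts), and then
    ratioed; smoothing counts before the ratio keeps sparse offsets stable.
    """
    w0, w1 = window
    if not (w0 <= 0 <= w1):
        raise ValueError("window must contain offset 0 (the TSS)")
    n = w1 - w0 + 1
    offsets = np.arange(w0, w1 + 1)
    counts_0 = {r: np.zeros(n, dtype=np.int64) for r in ROLES}
    counts_t = {r: np.zeros(n, dtype=np.int64) for r in ROLES}
    dyad_sum = np.zeros(n) if dyads is not None else None

    dense: dict[tuple[int, str, str], np.ndarray] = {}

    def _dense(track_id: int, track: LesionTrack, chrom: str, strand: str):
        key = (track_id, chrom, strand)
        if key not in dense:
            dense[key] = track.to_dense(chrom, strand, chrom_lengths[chrom])
        return dense[key]

    dyad_dense: dict[str, np.ndarray] = {}
    n_genes = 0
    for g in genes:
        L = chrom_lengths[g.chrom]
        n_genes += 1
        if dyads is not None and g.chrom not in dyad_dense:
            arr = np.zeros(L)
            d = np.asarray(dyads.get(g.chrom, ()), dtype=np.int64)
            if d.size:
                arr[d] = 1.0
            dyad_dense[g.chrom] = arr
        if g.strand == "+":
            lo, hi = g.tss + w0, g.tss + w1 + 1
            src_lo, src_hi = max(lo, 0), min(hi, L)
            sl = slice(src_lo - lo, src_lo - lo + (src_hi - src_lo))
            take = slice(src_lo, src_hi)
            flip = False
        else:
            lo, hi = g.tss - w1, g.tss - w0 + 1
            src_lo, src_hi = max(lo, 0), min(hi, L)
            # genomic tss - o maps to offset o; reversed slice
            sl = slice(hi - src_hi, hi - src_hi + (src_hi - src_lo))
            take = slice(src_lo, src_hi)
            flip = True
        for role, strand in (("TS", g.ts_strand), ("NTS", g.nts_strand)):
            a0 = _dense(0, track_0, g.chrom, strand)[take]
            at = _dense(1, track_t, g.chrom, strand)[take]
            if flip:
                a0, at = a0[::-1], at[::-1]
            counts_0[role][sl] += a0
            counts_t[role][sl] += at
        if dyad_sum is not None:
            dv = dyad_dense[g.chrom][take]
            if flip:
                dv = dv[::-1]
            dyad_sum[sl] += dv

    fractions = {}
    for role in ROLES:
        s0 = _moving_average(counts_0[role], smooth)
        st = _moving_average(counts_t[role], smooth)
        with np.errstate(divide="ignore", invalid="ignore"):
            fractions[role] = np.where(s0 > 0, st / np.where(s0 > 0, s0, 1),
                                       np.nan) * scale_factor
    dyad_cov = dyad_sum / max(n_genes, 1) if dyad_sum is not None else None
    return SingleNtProfile(offsets=offsets, fractions=fractions,
                           counts_0=counts_0, counts_t=counts_t,
                           dyad_coverage=dyad_cov, n_genes=n_genes,
                           smooth=smooth, scale_factor=scale_factor)


# ---------------------------------------------------------------------------
# gene x bin matrix and SRAT stratification
# ---------------------------------------------------------------------------

_ORDER_KEYS = ("transcription_rate", "expr_log2fc", "srat_first")


def _per_gene_fractions(track_t: LesionTrack, track_0: LesionTrack,
                        gene: GeneModel, flank_bin_bp: int, n_body_bins: int,
                        scale_factor: float) -> dict[str, float]:
    bins = gene_bins(gene, flank_bin_bp, n_body_bins)
    row = {}
    for role, strand in (("TS", gene.ts_strand), ("NTS", gene.nts_strand)):
        for i, (s, e) in enumerate(bins):
            c0 = track_0.region_sum(gene.chrom, strand, s, e)
            ct = track_t.region_sum(gene.chrom, strand, s, e)
            row[f"{role}_bin{i + 1:02d}"] = (ct / c0 * scale_factor
                                             if c0 > 0 else np.nan)
    return row


def gene_matrix(track_t: LesionTrack, track_0: LesionTrack,
                genes: Sequence[GeneModel],
                order_key: str = "transcription_rate",
                reference_pair: Optional[tuple[LesionTrack, LesionTrack]] = None,
                flank_bin_bp: int = 167, n_body_bins: int = 6,
                scale_factor: float = 1.0, ref_scale_factor: float = 1.0,
                denylist: Sequence[str] = ()) -> GeneRepairMatrix:
    """Per-gene, per-bin fractions remaining (or test - reference
    differences), rows ordered for heatmap display.

    ``order_key``: ``transcription_rate`` (descending), ``expr_log2fc``
    (ascending fold-change) or ``srat_first`` (SRAT genes at the top, then
    by transcription rate).  Genes missing the covariate sort last.
    """
    if order_key not in _ORDER_KEYS:
        raise ValueError(f"order_key must be one of {_ORDER_KEYS}")
    kept = _filter_genes(genes, n_body_bins, denylist)
    rows = {}
    for g in kept:
        row = _per_gene_fractions(track_t, track_0, g, flank_bin_bp,
                                  n_body_bins, scale_factor)
        if reference_pair is not None:
            ref_row = _per_gene_fractions(reference_pair[0], reference_pair[1],
                                          g, flank_bin_bp, n_body_bins,
                                          ref_scale_factor)
            row = {k: row[k] - ref_row[k] for k in row}
        rows[g.gene_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"

    by_id = {g.gene_id: g for g in kept}
    n_missing = 0

    def sort_tuple(gid: str):
        nonlocal n_missing
        g = by_id[gid]
        rate = g.transcription_rate
        if order_key == "transcription_rate":
            if rate is None:
                n_missing += 1
                return (1, 0.0)
            return (0, -rate)
        if order_key == "expr_log2fc":
            if g.expr_log2fc is None:
                n_missing += 1
                return (1, 0.0)
            return (0, g.expr_log2fc)
        # srat_first
        return (0 if g.is_srat else 1, -(rate if rate is not None else -np.inf))

    order = sorted(df.index, key=sort_tuple)
    if n_missing:
        logger.info("gene matrix: %d genes missing %s placed last",
                    n_missing, order_key)
    return GeneRepairMatrix(data=df.loc[order], order_key=order_key,
                            is_difference=reference_pair is not None)


def srat_contrast(matrix: GeneRepairMatrix,
                  srat_labels: Mapping[str, bool],
                  roles: Sequence[str] = ("NTS", "TS"),
                  n_boot: int = 1000, seed: int = 0,
                  ci_level: float = 0.95) -> pd.DataFrame:
    """Per-body-bin mean of SRAT genes vs the rest, with a nonparametric
    bootstrap CI on the difference of means (resampling genes).

    On a difference matrix (mutant - control) this quantifies how much more
    the NTS of SRAT genes changed than the rest of the genome.
    """
    labels = pd.Series({gid: bool(srat_labels[gid])
                        for gid in matrix.data.index})
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise ValueError("both SRAT and non-SRAT groups must be non-empty")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    for role in roles:
        for i in BODY_IDX:
            col = f"{role}_bin{i + 1:02d}"
            a = matrix.data.loc[labels.values, col].dropna().to_numpy()
            b = matrix.data.loc[~labels.values, col].dropna().to_numpy()
            if a.size == 0 or b.size == 0:
                raise ValueError(f"empty group in {col}")
            diff = a.mean() - b.mean()
            ia = rng.integers(0, a.size, size=(n_boot, a.size))
            ib = rng.integers(0, b.size, size=(n_boot, b.size))
            boot = a[ia].mean(axis=1) - b[ib].mean(axis=1)
            lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
            rows.append({"strand_role": role, "bin": i + 1,
                         "mean_srat": a.mean(), "mean_rest": b.mean(),
                         "difference": diff, "ci_lo": lo, "ci_hi": hi,
                         "n_srat": a.size, "n_rest": b.size})
    return pd.DataFrame(rows)
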