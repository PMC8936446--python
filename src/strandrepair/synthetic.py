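"""Parametric simulator of UV lesion induction and strand-specific repair.

The generator produces a random genome, a non-overlapping gene annotation
with covariates, nucleosome dyad positions, and CPD lesion tracks at 0 hr and
at later repair timepoints, under a simple kinetic model:

* **Induction.**  Every dipyrimidine site (TT/TC/CT/CC) on either strand
  independently carries a lesion with a dinucleotide-specific probability.
  The lesion is keyed by the 5'-most base of the dinucleotide on the damaged
  strand.

* **Repair.**  Each lesion at position x on strand s survives to time t with
  probability exp(-k(x,s) * t), where

      k(x,s) = m_nuc(x) * k_gg * g_gg
             + k_tc   * g_tc   * [s is the TS of a covering gene]
             + k_anti * g_anti * [s is the NTS of a covering SRAT gene]

  m_nuc(x) = 1 - nuc_amplitude * c(x) slows global-genome repair (GG-NER)
  inside nucleosomes; c(x) is a cosine-interpolated dyad-proximity weight
  (1 at a dyad, 0 at the linker midpoint).  The g_* factors are genotype
  multipliers on the GG-NER, transcription-coupled (TC-NER) and antisense
  TC-NER rates.  The SRAT term models cryptic antisense transcription of
  Set2-repressed antisense transcript genes, which recruits TC-NER to the
  non-transcribed strand once SET2 is deleted.

* **Sequencing depth.**  Observed counts are a binomial thinning of true
  lesion counts so that the expected library size matches ``depth``.

Per-lesion survival uniforms are drawn in a fixed order that depends only on
the seed, not on t, so repair timepoints simulated with the same seed are
nested: a lesion repaired by t1 is also absent at every t2 > t1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import GeneModel, LesionTrack, seq_to_codes
from .gel import BulkRepairCurve, GelLane, curve_from_fractions

#: genotype -> (g_gg, g_tc, g_anti) rate multipliers.  ``gamma_tc`` = 0.4
#: encodes that loss of Set2/H3K36me impairs but does not abolish TC-NER;
#: deleting SET2 also de-represses antisense transcription (g_anti = 1).
GAMMA_TC = 0.4
GENOTYPE_PRESETS: dict[str, tuple[float, float, float]] = {
    "WT": (1.0, 1.0, 0.0),
    "set2": (1.0, GAMMA_TC, 1.0),
    "rad16": (0.0, 1.0, 0.0),
    "rad16set2": (0.0, GAMMA_TC, 1.0),
    "rad26": (1.0, 0.0, 0.0),
}

#: relative CPD induction probabilities per dipyrimidine; TT dimers form most
#: readily, CC least.  Values give a realistic genome-wide lesion density of
#: roughly 0.03-0.04 lesions per bp of dipyrimidine sequence after a
#: UVC dose in the 100 J/m2 range.
DEFAULT_INDUCTION = {"TT": 0.10, "TC": 0.05, "CT": 0.05, "CC": 0.02}

#: yeast-like base composition (~38% GC)
DEFAULT_BASE_COMPOSITION = {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}


@dataclass
class SimulationConfig:
    """Parameters of the induction/repair simulation.

    Rates are per hour.  ``nuc_repeat`` is the nucleosome repeat length in bp
    (yeast ~165); ``first_dyad_offset`` places the +1 nucleosome dyad
    downstream of the TSS.  ``depth`` is the expected sampled reads per
    library.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (500, 2500)
    intergenic_min: int = 200
    base_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_COMPOSITION))
    induction_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDUCTION))
    k_gg: float = 0.2
    k_tc: float = 0.6
    k_anti: float = 0.3
    nuc_amplitude: float = 0.5
    nuc_repeat: int = 165
    first_dyad_offset: int = 60
    srat_fraction: float = 0.1
    depth: int = 200_000
    genotype_presets: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GENOTYPE_PRESETS))

    def __post_init__(self) -> None:
        comp = np.array([self.base_composition[b] for b in "ACGT"], dtype=float)
        if not np.isclose(comp.sum(), 1.0):
            raise ValueError("base_composition must sum to 1")
        for d, p in self.induction_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"induction_prob[{d}] must be in [0,1]")
        for name, k in (("k_gg", self.k_gg), ("k_tc", self.k_tc),
                        ("k_anti", self.k_anti)):
            if k < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.nuc_amplitude <= 1.0:
            raise ValueError("nuc_amplitude must be in [0,1]")
        if not 0.0 <= self.srat_fraction <= 1.0:
            raise ValueError("srat_fraction must be in [0,1]")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be a positive pair lo<=hi")


@dataclass
class GroundTruth:
    """Everything the simulator knows, for parameter-recovery checks."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    dyads: dict[str, np.ndarray]  # sorted dyad positions per chrom
    lesions_0hr: Optional[LesionTrack] = None
    lesions_t: dict[float, LesionTrack] = field(default_factory=dict)
    true_rates: dict[str, dict[tuple[str, str], np.ndarray]] = field(
        default_factory=dict)
    bulk_fraction_remaining: dict[float, float] = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def dyad_coverage(self) -> dict[str, np.ndarray]:
        """Dense 0/1 dyad indicator per chromosome."""
        out = {}
        for chrom, length in self.chrom_lengths.items():
            arr = np.zeros(length, dtype=float)
            d = self.dyads.get(chrom)
            if d is not None and d.size:
                arr[d] = 1.0
            out[chrom] = arr
        return out


# ---------------------------------------------------------------------------
# genome / annotation generation
# ---------------------------------------------------------------------------

def generate_genome_and_genes(config: SimulationConfig) -> GroundTruth:
    """Random genome plus a packed, non-overlapping gene annotation.

    Genes are placed left to right with intergenic gaps of at least
    ``intergenic_min`` bp; leftover space is spread randomly over the gaps.
    Strands are drawn uniformly; exactly floor(srat_fraction * n_genes) genes
    get the SRAT flag.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    comp = np.array([config.base_composition[b] for b in "ACGT"], dtype=float)
    bases = np.array(list("ACGT"))

    genome: dict[str, str] = {}
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    for chrom in chrom_names:
        seq = rng.choice(bases, size=config.chrom_length, p=comp)
        genome[chrom] = "".join(seq.tolist())

    # split genes across chromosomes as evenly as possible
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gidx = 0
    for chrom, n in zip(chrom_names, per_chrom):
        if n == 0:
            continue
        lo, hi = config.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=n)
        needed = int(lengths.sum()) + (n + 1) * config.intergenic_min
        if needed > config.chrom_length:
            raise ValueError(
                f"infeasible packing on {chrom}: {n} genes need {needed} bp "
                f"but chrom_length is {config.chrom_length}")
        slack = config.chrom_length - needed
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for j in range(n):
            pos += config.intergenic_min + int(extra[j])
            start, length = pos, int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss, tes = start, start + length
            else:
                tss, tes = start + length - 1, start - 1
            genes.append(GeneModel(
                gene_id=f"g{gidx:04d}", chrom=chrom, strand=strand,
                tss=tss, tes=tes,
                transcription_rate=float(rng.lognormal(1.0, 1.0)),
                expr_log2fc=float(rng.normal(0.0, 1.0))))
            pos += length
            gidx += 1

    n_srat = int(np.floor(config.srat_fraction * config.n_genes))
    if n_srat > 0 and genes:
        srat_idx = rng.choice(len(genes), size=n_srat, replace=False)
        for i in srat_idx:
            genes[i].srat_class = "polyA"

    dyads = _place_dyads(genes, config, {c: len(genome[c]) for c in genome})
    return GroundTruth(config=config, genome=genome, genes=genes, dyads=dyads)


def _place_dyads(genes: Sequence[GeneModel], config: SimulationConfig,
                 chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Dyads at ``first_dyad_offset`` from each TSS, then every ``nuc_repeat``
    bp within the gene body, in transcription orientation."""
    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for g in genes:
        offsets = np.arange(config.first_dyad_offset, g.body_length,
                            config.nuc_repeat)
        if g.strand == "+":
            positions = g.tss + offsets
        else:
            positions = g.tss - offsets
        length = chrom_lengths[g.chrom]
        positions = positions[(positions >= 0) & (positions < length)]
        per_chrom[g.chrom].extend(positions.tolist())
    return {c: np.unique(np.array(v, dtype=np.int64))
            for c, v in per_chrom.items()}


# ---------------------------------------------------------------------------
# lesion induction
# ---------------------------------------------------------------------------

_DIPY_CODE = {"TT": 15, "TC": 13, "CT": 7, "CC": 5}  # code = 4*b0 + b1


def dipyrimidine_positions(seq: str) -> dict[str, np.ndarray]:
    """5'-most positions of every dipyrimidine on each strand, with the
    dinucleotide code at each position.

    Returns {"+": (positions, codes), "-": (positions, codes)} where codes
    index a 16-entry table (4*first + second, A=0 C=1 G=2 T=3 in 5'->3'
    order on the respective strand).
    """
    codes = seq_to_codes(seq)
    n = codes.size
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if n < 2:
        empty = (np.empty(0, np.int64), np.empty(0, np.int64))
        return {"+": empty, "-": empty}
    b0, b1 = codes[:-1], codes[1:]
    valid = (b0 < 4) & (b1 < 4)
    plus_code = (4 * b0 + b1).astype(np.int64)
    is_py = np.isin(plus_code, list(_DIPY_CODE.values())) & valid
    out["+"] = (np.flatnonzero(is_py).astype(np.int64), plus_code[is_py])
    # minus strand: dinucleotide with 5'-most base at j (j >= 1) reads
    # comp(base[j]), comp(base[j-1])
    c0, c1 = 3 - codes[1:], 3 - codes[:-1]  # at 5'-most position j = i+1
    validm = (codes[1:] < 4) & (codes[:-1] < 4)
    minus_code = (4 * c0 + c1).astype(np.int64)
    is_pym = np.isin(minus_code, list(_DIPY_CODE.values())) & validm
    idx = np.flatnonzero(is_pym).astype(np.int64) + 1
    out["-"] = (idx, minus_code[is_pym])
    return out


def induce_lesions(genome: Mapping[str, str], config: SimulationConfig,
                   seed: int) -> LesionTrack:
    """Bernoulli lesion induction at every dipyrimidine site on both strands.

    The lesion is recorded at the 5'-most base of the dinucleotide on the
    damaged strand.  Non-dipyrimidine sites never carry lesions.
    """
    rng = np.random.default_rng(seed)
    prob16 = np.zeros(16)
    for d, p in config.induction_prob.items():
        prob16[_DIPY_CODE[d]] = p
    track = LesionTrack(sample_id="sim", timepoint=0.0,
                        provenance=f"induced(seed={seed})")
    for chrom in sorted(genome):
        sites = dipyrimidine_positions(genome[chrom])
        for strand in "+-":
            pos, code = sites[strand]
            if pos.size == 0:
                continue
            hit = rng.random(pos.size) < prob16[code]
            track.set_counts(chrom, strand, pos[hit],
                             np.ones(int(hit.sum()), dtype=np.int64))
    return track


# ---------------------------------------------------------------------------
# repair kinetics
# ---------------------------------------------------------------------------

def repair_rate_field(genes: Sequence[GeneModel],
                      dyads: Mapping[str, np.ndarray],
                      config: SimulationConfig, genotype: str,
                      chrom_lengths: Mapping[str, int],
                      ) -> dict[tuple[str, str], np.ndarray]:
    """Dense per-position, per-strand repair rate k(x, s) for one genotype."""
    if genotype not in config.genotype_presets:
        raise ValueError(
            f"unknown genotype {genotype!r}; presets: "
            f"{sorted(config.genotype_presets)}")
    g_gg, g_tc, g_anti = config.genotype_presets[genotype]
    out: dict[tuple[str, str], np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        x = np.arange(length)
        # nucleosome modulation of GG-NER
        d = dyads.get(chrom, np.empty(0, np.int64))
        if d.size:
            idx = np.searchsorted(d, x)
            left = np.where(idx > 0, x - d[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
            right = np.where(idx < d.size, d[np.minimum(idx, d.size - 1)] - x,
                             np.iinfo(np.int64).max)
            dist = np.minimum(left, right).astype(float)
            c = np.where(dist <= config.nuc_repeat / 2.0,
                         0.5 * (1.0 + np.cos(2.0 * np.pi * dist / config.nuc_repeat)),
                         0.0)
        else:
            c = np.zeros(length)
        m_nuc = 1.0 - config.nuc_amplitude * c

        cg = [g for g in genes if g.chrom == chrom]
        starts = np.array([g.body_start for g in cg], dtype=np.int64)
        ends = np.array([g.body_end for g in cg], dtype=np.int64)
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        gstrand = np.array([cg[i].strand for i in order])
        gsrat = np.array([cg[i].is_srat for i in order])

        if starts.size:
            gi = np.searchsorted(starts, x, side="right") - 1
            covered = (gi >= 0) & (x < ends[np.maximum(gi, 0)])
            gi = np.maximum(gi, 0)
        else:
            covered = np.zeros(length, dtype=bool)
            gi = np.zeros(length, dtype=np.int64)

        for strand in "+-":
            k = m_nuc * config.k_gg * g_gg
            if starts.size:
                # TS: strand opposite the gene's coding strand
                is_ts = covered & (gstrand[gi] != strand)
                is_srat_nts = covered & (gstrand[gi] == strand) & gsrat[gi]
                k = k + np.where(is_ts, config.k_tc * g_tc, 0.0)
                k = k + np.where(is_srat_nts, config.k_anti * g_anti, 0.0)
            out[(chrom, strand)] = k
    return out


def simulate_repair(lesions_0: LesionTrack, genes: Sequence[GeneModel],
                    dyads: Mapping[str, np.ndarray], config: SimulationConfig,
                    genotype: str, t: float,
                    seed: int, chrom_lengths: Mapping[str, int],
                    rates: Optional[dict[tuple[str, str], np.ndarray]] = None,
                    ) -> LesionTrack:
    """Thin the 0 hr track by exponential survival exp(-k(x,s) t).

    With a fixed seed, survival uniforms depend only on lesion identity, so
    tracks at increasing t are nested.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if rates is None:
        rates = repair_rate_field(genes, dyads, config, genotype, chrom_lengths)
    rng = np.random.default_rng(seed)
    out = LesionTrack(sample_id=lesions_0.sample_id, timepoint=t,
                      provenance=f"repaired({genotype}, t={t}, seed={seed})")
    for chrom, strand in sorted(lesions_0._data):
        pos, cnt = lesions_0.get(chrom, strand)
        if pos.size == 0:
            continue
        k = rates[(chrom, strand)][pos]
        surv_p = np.exp(-k * t)
        # per-copy uniforms in a t-independent order -> nested timepoints
        u = rng.random(int(cnt.sum()))
        per_copy_p = np.repeat(surv_p, cnt)
        survived = u < per_copy_p
        offsets = np.concatenate([[0], np.cumsum(cnt)[:-1]])
        new_cnt = np.add.reduceat(survived.astype(np.int64), offsets)
        out.set_counts(chrom, strand, pos, new_cnt)
    return out


def sample_reads(track: LesionTrack, depth: int, seed: int) -> LesionTrack:
    """Binomial sequencing-depth thinning: each lesion copy is observed with
    probability min(1, depth / total), so the expected library size is
    ``depth`` (or everything, if depth exceeds the lesion total)."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    total = track.total_count
    out = track.copy(provenance=f"{track.provenance};thinned(depth={depth})")
    if total == 0:
        return out
    p = min(1.0, depth / total)
    if p >= 1.0:
        return out
    rng = np.random.default_rng(seed)
    for chrom, strand in sorted(track._data):
        pos, cnt = track.get(chrom, strand)
        new_cnt = rng.binomial(cnt, p)
        out.set_counts(chrom, strand, pos, new_cnt)
    return out


def simulate_timecourse(gt: GroundTruth, genotype: str,
                        timepoints: Sequence[float], seed: int,
                        depth: Optional[int] = None,
                        ) -> dict[float, LesionTrack]:
    """Induce lesions and repair them to each timepoint for one genotype.

    Returns {t: observed track}; 0 hr is always included.  Induction,
    survival and thinning use seeds derived from ``seed`` so different
    genotypes on the same ground truth share the 0 hr lesion field.
    """
    config = gt.config
    depth = config.depth if depth is None else depth
    if gt.lesions_0hr is None:
        gt.lesions_0hr = induce_lesions(gt.genome, config, seed=seed)
    rates = repair_rate_field(gt.genes, gt.dyads, config, genotype,
                              gt.chrom_lengths)
    gt.true_rates[genotype] = rates
    out: dict[float, LesionTrack] = {}
    ts = sorted(set([0.0] + [float(t) for t in timepoints]))
    for i, t in enumerate(ts):
        true_t = (gt.lesions_0hr if t == 0 else
                  simulate_repair(gt.lesions_0hr, gt.genes, gt.dyads, config,
                                  genotype, t, seed=seed + 1,
                                  chrom_lengths=gt.chrom_lengths, rates=rates))
        gt.lesions_t[t] = true_t
        if gt.lesions_0hr.total_count > 0:
            gt.bulk_fraction_remaining[t] = (true_t.total_count /
                                             gt.lesions_0hr.total_count)
        observed = sample_reads(true_t, depth, seed=seed + 2 + i)
        observed.timepoint = t
        observed.sample_id = f"{genotype}_{t:g}hr"
        out[t] = observed
    return out


# ---------------------------------------------------------------------------
# bulk (gel) curve and fragment-lane simulation
# ---------------------------------------------------------------------------

def simulate_gel_curve(gt: GroundTruth, timepoints: Sequence[float],
                       noise_sd: float = 0.0, n_replicates: int = 3,
                       seed: int = 0) -> BulkRepairCurve:
    """Bulk repair curve from the simulator's true genome-wide totals.

    Fraction remaining at t is total true lesions at t over the 0 hr total,
    plus optional Gaussian replicate noise truncated to [0, 1].
    """
    if gt.lesions_0hr is None or gt.lesions_0hr.total_count == 0:
        raise ValueError("no lesions at 0 hr; induce lesions first")
    rng = np.random.default_rng(seed)
    total0 = gt.lesions_0hr.total_count
    genome_kb = sum(gt.chrom_lengths.values()) * 2 / 1000.0  # both strands
    fractions: dict[float, list[float]] = {}
    for t in sorted(set([0.0] + [float(t) for t in timepoints])):
        if t not in gt.lesions_t:
            raise ValueError(f"no simulated track at t={t}")
        f = gt.lesions_t[t].total_count / total0
        reps = np.clip(f + rng.normal(0.0, noise_sd, size=n_replicates), 0.0, 1.0) \
            if noise_sd > 0 else np.full(n_replicates, f)
        fractions[t] = reps.tolist()
    return curve_from_fractions(fractions, cpds_per_kb_0hr=total0 / genome_kb)


def simulate_fragment_lane(cuts_per_kb: float, seed: int,
                           sample_id: str = "sim", enzyme: str = "plus",
                           mol_length_kb: float = 50.0,
                           n_molecules: int = 10_000,
                           n_bins: int = 300) -> GelLane:
    """Alkaline-gel lane from Poisson fragmentation of uniform molecules.

    Each molecule receives Poisson(cuts_per_kb * mol_length_kb) cuts at
    uniform positions; the lane profile is the fragment mass histogram mapped
    to migration distance with the log-linear mobility law
    migration = 60 - 20*log10(length bp).
    """
    rng = np.random.default_rng(seed)
    n_cuts = rng.poisson(cuts_per_kb * mol_length_kb, size=n_molecules)
    frags: list[np.ndarray] = []
    for nc in np.unique(n_cuts):
        mols = np.flatnonzero(n_cuts == nc)
        if nc == 0:
            frags.append(np.full(mols.size, mol_length_kb))
            continue
        cuts = np.sort(rng.random((mols.size, nc)), axis=1) * mol_length_kb
        bounds = np.concatenate([np.zeros((mols.size, 1)), cuts,
                                 np.full((mols.size, 1), mol_length_kb)], axis=1)
        frags.append(np.diff(bounds, axis=1).ravel())
    lengths_kb = np.concatenate(frags)
    lengths_kb = lengths_kb[lengths_kb > 1e-6]
    log_bp = np.log10(lengths_kb * 1000.0)
    edges = np.linspace(log_bp.min() - 1e-9, log_bp.max() + 1e-9, n_bins + 1)
    mass, _ = np.histogram(log_bp, bins=edges, weights=lengths_kb)
    centers_bp = 10.0 ** ((edges[:-1] + edges[1:]) / 2.0)
    migration = 60.0 - 20.0 * np.log10(centers_bp)
    order = np.argsort(migration)
    profile = np.column_stack([migration[order], mass[order]])
    ladder_bp = np.array([100_000.0, 10_000.0, 1_000.0, 100.0, 10.0])
    ladder = np.column_stack([60.0 - 20.0 * np.log10(ladder_bp), ladder_bp])
    return GelLane(sample_id=sample_id, enzyme=enzyme,
                   profile=profile, ladder=ladder)


def reads_from_lesions(track: LesionTrack, chrom_lengths: Mapping[str, int],
                       ) -> tuple[list[tuple[str, int, str, int]], int]:
    """Fabricate read 5'-end records that would map back to this track.

    Inverts the lesion-calling offset convention: a lesion on the minus
    strand at its 5'-most base p is detected by a *plus*-strand read whose
    5' end is p + 1; a plus-strand lesion at p by a minus-strand read at
    p - 1.  Returns (records, n_unrepresentable): lesions at the extreme
    chromosome ends (plus-strand position 0, minus-strand position L-1)
    have no valid read coordinate and are skipped with a tally.
    """
    records: list[tuple[str, int, str, int]] = []
    skipped = 0
    for chrom, strand in sorted(track._data):
        length = chrom_lengths[chrom]
        pos, cnt = track.get(chrom, strand)
        for p, c in zip(pos.tolist(), cnt.tolist()):
            if strand == "+":
                rp, rs = p - 1, "-"
            else:
                rp, rs = p + 1, "+"
            if 0 <= rp < length:
                records.append((chrom, rp, rs, c))
            else:
                skipped += c
    return records, skipped
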