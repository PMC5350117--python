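"""Synthetic validation-study inputs with the structure the analysis assumes.

Generates, fully determined by a seed: exon-level target geometry with
splice padding and a SegDup subset; a genotype-known truth callset over the
targets; evaluation callsets with planted false-positive, false-negative and
genotype-error rates; overdispersed per-base depth tracks whose mean depends
on run plexity (single-sample runs roughly 300x, three-sample pools roughly
118x) and which systematically depress first exons (the GC-capture-loss
signature); and replicate series spanning intra-run, inter-run,
inter-operator, inter-lot and inter-day comparisons.

All artifacts round-trip through panelval.io as plain text (VCF, BED, TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .concordance import CallSet, GenotypeClass, VariantKey
from .coverage import DepthTrack
from .regions import RegionIndex, SegDupRegion, TargetRegion, pad_splice
from .registry import PanelDefinition
from .variability import ReplicateLabel

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic validation study.

    Defaults mirror the validated comprehensive-panel regime: 61 genes,
    single-sample mean depth 301.25x vs three-sample 117.48x with a
    negative-binomial dispersion wide enough to match observed run-to-run
    spread, a planted 0.07 FP / 0.04 FN error structure, and a depressed
    first exon (multiplier 0.3).
    """

    seed: int = 0
    n_genes: int = 61
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (90, 240)
    n_truth_variants: int = 5000
    het_fraction: float = 0.6
    fp_rate: float = 0.07
    fn_rate: float = 0.04
    genotype_error_rate: float = 0.01
    mean_depth_1plex: float = 301.25
    mean_depth_3plex: float = 117.48
    depth_dispersion: float = 60.0
    first_exon_depth_multiplier: float = 1.0
    segdup_fraction: float = 0.0
    n_replicates: int = 4
    replicate_noise: float = 0.01

    def __post_init__(self) -> None:
        for name in ("het_fraction", "fp_rate", "fn_rate",
                     "genotype_error_rate", "first_exon_depth_multiplier",
                     "segdup_fraction", "replicate_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent deterministic generator per generation stage.

    Uses a stable string digest (built-in hash() is salted per process and
    would break byte-identical reproduction across runs).
    """
    digest = sum((i + 1) * ord(c) for i, c in enumerate(stream)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


@dataclass
class ReferencePanel:
    targets: list[TargetRegion]
    segdups: list[SegDupRegion]
    panel: PanelDefinition

    @property
    def index(self) -> RegionIndex:
        return RegionIndex(self.targets)


def make_reference_panel(config: SimulationConfig) -> ReferencePanel:
    """Non-overlapping exon targets (with 2 nt splice padding) per gene.

    Genes are laid out sequentially on a synthetic chromosome with fixed
    intergenic and intronic gaps, so regions can never collide;
    `segdup_fraction` of exons are additionally marked as SegDup intervals
    (none of them pre-validated).
    """
    rng = _stream_rng(config.seed, "geometry")
    lo_e, hi_e = config.exons_per_gene
    lo_l, hi_l = config.exon_length
    if lo_e < 1 or lo_l < 10:
        raise ValueError("infeasible geometry")
    targets: list[TargetRegion] = []
    cursor = 1000
    intron, intergenic = 300, 5000
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:03d}"
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        for e in range(1, n_exons + 1):
            length = int(rng.integers(lo_l, hi_l + 1))
            exon = TargetRegion("chrS", cursor, cursor + length, gene, e)
            targets.append(pad_splice(exon))
            cursor += length + intron
        cursor += intergenic
    segdups: list[SegDupRegion] = []
    if config.segdup_fraction > 0:
        mask = rng.random(len(targets)) < config.segdup_fraction
        segdups = [SegDupRegion(t.chrom, t.start, t.end, False)
                   for t, m in zip(targets, mask) if m]
    panel = PanelDefinition(
        name="SIM",
        genes=frozenset(t.gene for t in targets))
    return ReferencePanel(targets=targets, segdups=segdups, panel=panel)


def simulate_truth(targets: list[TargetRegion], config: SimulationConfig,
                   sample_id: str = "TRUTH") -> CallSet:
    """Genotype-known truth callset: variants uniform over target bases.

    Sites are collision-free; genotype is het with probability
    `het_fraction`, else hom-alt.  Assessed regions are the full target set,
    so absence elsewhere on target means hom-ref.
    """
    rng = _stream_rng(config.seed, "truth")
    index = RegionIndex(targets)
    all_positions = [(t.chrom, p) for t in sorted(targets)
                     for p in t.positions()]
    if config.n_truth_variants > len(all_positions):
        raise ValueError("more variants requested than target bases")
    chosen = rng.choice(len(all_positions), size=config.n_truth_variants,
                        replace=False)
    calls: dict[VariantKey, GenotypeClass] = {}
    for i in sorted(int(c) for c in chosen):
        chrom, pos = all_positions[i]
        ref, alt = rng.choice(4, size=2, replace=False)
        gt = (GenotypeClass.HET if rng.random() < config.het_fraction
              else GenotypeClass.HOM_ALT)
        calls[VariantKey(chrom, pos, str(_BASES[ref]), str(_BASES[alt]))] = gt
    return CallSet(sample_id=sample_id, calls=calls, assessed_regions=index)


def simulate_eval(truth: CallSet, config: SimulationConfig,
                  sample_id: str = "EVAL",
                  stream: str = "eval") -> CallSet:
    """Evaluation callset with planted FP / FN / genotype-error structure.

    Each truth variant is dropped (silently hom-ref) with probability
    `fn_rate` and genotype-flipped het<->hom-alt with probability
    `genotype_error_rate`; Binomial(n_truth, fp_rate) spurious non-reference
    calls are added at distinct non-variant target positions.
    """
    if not truth.calls:
        raise ValueError("truth callset is empty")
    rng = _stream_rng(config.seed, stream)
    calls: dict[VariantKey, GenotypeClass] = {}
    for key in sorted(truth.calls):
        gt = truth.calls[key]
        if rng.random() < config.fn_rate:
            continue  # missed variant: implicit hom-ref
        if rng.random() < config.genotype_error_rate:
            gt = (GenotypeClass.HOM_ALT if gt is GenotypeClass.HET
                  else GenotypeClass.HET)
        calls[key] = gt

    n_fp = int(rng.binomial(len(truth.calls), config.fp_rate))
    if n_fp:
        taken = {(k.chrom, k.pos) for k in truth.calls}
        free = [(t.chrom, p) for t in sorted(truth.assessed_regions)
                for p in t.positions() if (t.chrom, p) not in taken]
        chosen = rng.choice(len(free), size=min(n_fp, len(free)),
                            replace=False)
        for i in sorted(int(c) for c in chosen):
            chrom, pos = free[i]
            ref, alt = rng.choice(4, size=2, replace=False)
            gt = (GenotypeClass.HET if rng.random() < 0.5
                  else GenotypeClass.HOM_ALT)
            calls[VariantKey(chrom, pos, str(_BASES[ref]),
                             str(_BASES[alt]))] = gt
    return CallSet(sample_id=sample_id, calls=calls,
                   assessed_regions=truth.assessed_regions)


def plant_indels(callset: CallSet, hom_lengths: list[int],
                 het_lengths: list[int], seed: int = 0) -> CallSet:
    """Add deletions of exactly the given lengths (for detection-limit tests).

    Lengths are |len(ref) - len(alt)|, so maxima are exactly known.
    Planted at positions beyond existing calls on the same chromosome.
    """
    rng = np.random.default_rng(seed)
    calls = dict(callset.calls)
    chrom = next(iter(calls)).chrom if calls else "chrS"
    base = (max(k.pos for k in calls) if calls else 0) + 1000
    for offset, (length, gt) in enumerate(
            [(l, GenotypeClass.HOM_ALT) for l in hom_lengths]
            + [(l, GenotypeClass.HET) for l in het_lengths]):
        anchor = str(_BASES[rng.integers(4)])
        deleted = "".join(_BASES[rng.integers(4, size=length)])
        key = VariantKey(chrom, base + offset * 200, anchor + deleted, anchor)
        calls[key] = gt
    return CallSet(sample_id=callset.sample_id, calls=calls,
                   assessed_regions=callset.assessed_regions)


def simulate_depth(targets: list[TargetRegion], config: SimulationConfig,
                   plex: int = 1, stream: str = "depth") -> DepthTrack:
    """Overdispersed per-base depth over the targets.

    Depth ~ NegativeBinomial with mean `mean_depth_{plex}` scaled by
    `first_exon_depth_multiplier` for exon index 1, and dispersion
    `depth_dispersion` (variance = mu + mu^2/dispersion).
    """
    if plex not in (1, 3):
        raise ValueError("plex must be 1 or 3")
    rng = _stream_rng(config.seed, f"{stream}:{plex}")
    base_mean = (config.mean_depth_1plex if plex == 1
                 else config.mean_depth_3plex)
    k = config.depth_dispersion
    track = DepthTrack()
    for t in sorted(targets):
        mu = base_mean * (config.first_exon_depth_multiplier
                          if t.exon_index == 1 else 1.0)
        if mu <= 0:
            depths = np.zeros(t.length, dtype=np.int64)
        else:
            depths = rng.negative_binomial(k, k / (k + mu), size=t.length)
        for pos, d in zip(t.positions(), depths):
            track.set(t.chrom, pos, int(d))
    return track


def simulate_replicates(truth: CallSet, config: SimulationConfig,
                        ) -> list[tuple[ReplicateLabel, CallSet]]:
    """Replicate callsets of one sample spanning all variability groupings.

    Replicates share the truth variants and receive independent error draws
    at `replicate_noise` scale; labels cycle runs, operators, lots and days
    so intra-run, inter-run, inter-operator, inter-lot and inter-day pairs
    all occur (the first two replicates share a run).
    """
    if config.n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    noise_cfg = replace(config, fp_rate=config.replicate_noise,
                        fn_rate=config.replicate_noise,
                        genotype_error_rate=config.replicate_noise)
    out = []
    for i in range(config.n_replicates):
        run = "RUN1" if i < 2 else f"RUN{i}"
        label = ReplicateLabel(
            sample_id=truth.sample_id,
            run_id=run,
            operator="A" if i % 2 == 0 else "B",
            reagent_lot=f"lot{1 + (i // 2) % 2}",
            day=f"day{1 + i // 2}",
            plex=1,
        )
        calls = simulate_eval(truth, noise_cfg,
                              sample_id=f"{truth.sample_id}_rep{i + 1}",
                              stream=f"replicate:{i}")
        out.append((label, calls))
    return out
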