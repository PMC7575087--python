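"""Synthetic-data generator for the ohnologue-divergence pipeline.

Emulates the three data shapes the pipeline consumes, with recorded ground
truth so every downstream stage can be validated against a known answer:

* rooted gene trees containing a salmonid-specific duplication node with a
  Northern-pike sister lineage and non-salmonid outgroups (newick, leaf
  labels ``gene|species|chr:start-end``);
* Ss4R collinear-block tables with 1-Mbp windowed percent sequence
  similarity, whose level encodes rediploidization timing (early ~87 %,
  mid 90-95 %, late >95 %);
* negative-binomial count matrices for four experimental designs: a
  multi-tissue atlas, a diel/circadian time course (light-dark plus
  constant light or dark), a six-stage smoltification time course, and a
  freshwater-vs-seawater challenge.

No nucleotide or read-level data is simulated; trees, coordinates and
counts are the substrate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ExpressionBundle",
    "simulate_gene_trees",
    "simulate_synteny",
    "simulate_expression",
    "archetype_profiles",
    "write_trees",
    "write_ground_truth",
]

SIMILARITY_CLASSES = ("early", "mid", "late")
#: topology/locus defects a negative orthogroup can exemplify
VIOLATION_MODES = (
    "lost_duplicate",    # one Ss4R copy lost: single focal gene, clean clade
    "criterion_i",       # outgroup leaf intrudes into the salmonid clade
    "criterion_ii",      # sister of the salmonid clade is not (only) pike
    "criterion_iii",     # no other salmonid retains a mirrored pair
    "no_synteny",        # topology fine but loci fall outside Ss4R blocks
)


@dataclass
class SimulationConfig:
    """Knobs for the generator; defaults mirror the study designs.

    ``timepoints`` is interpreted per design: hours for ``circadian``
    (ignored: the fixed sampling schedules below are used), stage labels
    for ``smolt``. Amplitudes and effects are on the log2 scale.
    """

    seed: int = 0
    n_orthogroups: int = 50
    salmonids: tuple[str, ...] = ("ssal", "omyk", "salp")
    focal: str = "ssal"
    pike: str = "eluc"
    outgroups: tuple[str, ...] = ("drer", "olat")
    p_loss_post_wgd: float = 0.0
    similarity_class_mix: dict[str, float] = field(
        default_factory=lambda: {"early": 1 / 3, "mid": 1 / 3, "late": 1 / 3}
    )
    tissues: tuple[str, ...] = ("OT", "gill", "SV")
    design: str = "circadian"
    timepoints: tuple = ()
    n_replicates: int = 3
    frac_rhythmic: float = 0.3
    amplitude_lognormal: tuple[float, float] = (math.log(2.0), 0.25)
    damping_per_tissue: dict[str, float] = field(default_factory=dict)
    n_archetypes: int = 5
    frac_regulated: float = 0.5
    frac_divergent_pairs: float = 0.3
    sw_effect_log2fc: tuple[float, float] = (2.0, 0.5)
    frac_sw_responsive: float = 0.3
    nb_dispersion: float = 0.05
    mean_log2_expression: tuple[float, float] = (5.0, 1.5)
    noise_sd_log2: float = 0.0
    library_size: float = 1.0e6

    def validate(self) -> None:
        if len(self.salmonids) < 2:
            raise ValueError("species partition needs >=2 salmonid species")
        if not self.pike:
            raise ValueError("species partition is missing the pike lineage")
        if len(self.outgroups) < 1:
            raise ValueError("species partition is missing outgroups")
        if self.focal not in self.salmonids:
            raise ValueError("focal species must be one of the salmonids")
        if not 0.0 <= self.p_loss_post_wgd <= 1.0:
            raise ValueError("p_loss_post_wgd must lie in [0, 1]")
        mix = self.similarity_class_mix
        if set(mix) != set(SIMILARITY_CLASSES) or any(v < 0 for v in mix.values()):
            raise ValueError("similarity_class_mix must cover early/mid/late with non-negative weights")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("similarity_class_mix must sum to 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name, frac in (
            ("frac_rhythmic", self.frac_rhythmic),
            ("frac_regulated", self.frac_regulated),
            ("frac_divergent_pairs", self.frac_divergent_pairs),
            ("frac_sw_responsive", self.frac_sw_responsive),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted truth recorded while simulating; keys are gene ids."""

    true_pairs: list[dict] = field(default_factory=list)
    true_singletons: list[str] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)
    negative_cases: dict[str, str] = field(default_factory=dict)
    loci: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    pair_class: dict[str, str] = field(default_factory=dict)
    rhythmic_genes: dict[str, dict] = field(default_factory=dict)
    archetype_of_gene: dict[str, int] = field(default_factory=dict)
    sw_responsive: dict[str, float] = field(default_factory=dict)
    divergent_pairs: dict[str, str] = field(default_factory=dict)

    @property
    def gene_universe(self) -> list[str]:
        genes: list[str] = []
        for p in self.true_pairs:
            genes.extend([p["gene1"], p["gene2"]])
        genes.extend(self.true_singletons)
        return genes

    def pair_id(self, rec: dict) -> str:
        return rec["orthogroup"]


@dataclass
class ExpressionBundle:
    """Counts matrix (genes x samples) plus per-sample metadata.

    ``meta`` is indexed by sample id with columns tissue, condition, time,
    replicate; ``norm_factors`` default to 1 until TMM is applied.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    norm_factors: pd.Series | None = None
    #: the library sizes the generator actually drew (unavailable for real
    #: data, where column totals + TMM stand in); lets tests separate
    #: normalization error from planted effects
    true_library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("metadata rows must match count columns in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        elif (self.norm_factors <= 0).any():
            raise ValueError("norm_factors must be positive")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)


# ---------------------------------------------------------------------------
# RNG streams: one per artifact so adding a stage never perturbs another
# ---------------------------------------------------------------------------

_STREAM_OFFSETS = {"trees": 1, "synteny": 2, "expression": 3}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), _STREAM_OFFSETS[stream]])


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

_GENE_SPAN = 10_000  # bp footprint of a simulated gene
_BLOCK_SPAN = 3_000_000  # one collinear block per true pair


def _leaf(gene: str, species: str, chrom: str, start: int, end: int) -> str:
    # quoted so the colon in chr:start-end survives newick parsing
    return f"'{gene}|{species}|{chrom}:{start}-{end}'"


def _locus_for(index: int, chrom: str, rng: np.random.Generator) -> tuple[str, int, int]:
    block_start = 1 + index * _BLOCK_SPAN
    start = block_start + int(rng.integers(0, _BLOCK_SPAN - _GENE_SPAN))
    return chrom, start, start + _GENE_SPAN - 1


def simulate_gene_trees(config: SimulationConfig) -> tuple[dict[str, str], GroundTruth]:
    """Emit one rooted newick string per orthogroup plus planted truth.

    With probability ``1 - p_loss_post_wgd`` the orthogroup yields a bona
    fide Ss4R pair: a salmonid-only clade split into two duplicate
    sub-clades (each holding one copy per salmonid), pike as sister, and
    both focal loci inside a collinear block. Otherwise one copy is
    treated as lost and the emitted topology exemplifies one defect drawn
    from :data:`VIOLATION_MODES`, recorded per orthogroup so the caller
    can be tested per criterion.
    """

    config.validate()
    rng = _rng(config, "trees")
    truth = GroundTruth()
    trees: dict[str, str] = {}
    other_salmonids = [s for s in config.salmonids if s != config.focal]
    class_names = list(SIMILARITY_CLASSES)
    class_probs = [config.similarity_class_mix[c] for c in class_names]

    for i in range(config.n_orthogroups):
        og = f"OG{i:04d}"
        chrom_a, chrom_b = f"ssa{2 * (i % 5) + 1:02d}", f"ssa{2 * (i % 5) + 2:02d}"
        is_negative = rng.random() < config.p_loss_post_wgd
        mode = VIOLATION_MODES[rng.integers(len(VIOLATION_MODES))] if is_negative else None
        block_slot = i // 5  # position of this orthogroup along its chromosome pair

        g1 = f"{og}_{config.focal}_a"
        g2 = f"{og}_{config.focal}_b"
        locus1 = _locus_for(block_slot, chrom_a, rng)
        locus2 = _locus_for(block_slot, chrom_b, rng)
        if mode == "no_synteny":
            # second copy dropped onto a chromosome no block covers
            locus2 = _locus_for(block_slot, "ssa99", rng)

        def other_leaf(species: str, copy: str) -> str:
            c = str(rng.integers(1, 30))
            s = int(rng.integers(1, 50_000_000))
            return _leaf(f"{og}_{species}_{copy}", species, c, s, s + _GENE_SPAN - 1)

        leaf1 = _leaf(g1, config.focal, *locus1)
        leaf2 = _leaf(g2, config.focal, *locus2)

        def subclade(copy: str, focal_leaf: str, extra_salmonids=other_salmonids) -> str:
            node = focal_leaf
            for sp in extra_salmonids:
                node = f"({node},{other_leaf(sp, copy)})"
            return node

        pike = other_leaf(config.pike, "a")
        outs = [other_leaf(sp, "a") for sp in config.outgroups]

        if mode is None or mode == "no_synteny":
            clade = f"({subclade('a', leaf1)},{subclade('b', leaf2)})"
            core = f"({clade},{pike})"
        elif mode == "lost_duplicate":
            core = f"({subclade('a', leaf1)},{pike})"
        elif mode == "criterion_i":
            intruder = other_leaf(config.outgroups[0], "x")
            clade = f"({subclade('a', leaf1)},({subclade('b', leaf2)},{intruder}))"
            core = f"({clade},{pike})"
        elif mode == "criterion_ii":
            clade = f"({subclade('a', leaf1)},{subclade('b', leaf2)})"
            if rng.random() < 0.5:  # mixed sister: pike plus an outgroup leaf
                core = f"({clade},({pike},{other_leaf(config.outgroups[0], 'y')}))"
            else:  # pike absent from the sister position entirely
                core = f"(({clade},{other_leaf(config.outgroups[0], 'y')}),{pike})"
        elif mode == "criterion_iii":
            # duplicate sub-clades hold focal genes only: conservation fails
            clade = f"({leaf1},{leaf2})"
            core = f"({clade},{pike})"
        else:  # pragma: no cover
            raise AssertionError(mode)

        newick = core
        for out in outs:
            newick = f"({newick},{out})"
        trees[og] = newick + ";"

        truth.loci[g1] = locus1
        if mode is None or mode == "no_synteny":
            truth.loci[g2] = locus2
        if mode is None:
            cls = class_names[rng.choice(len(class_names), p=class_probs)]
            lo, hi = sorted([g1, g2], key=lambda g: (truth.loci[g][0], truth.loci[g][1]))
            truth.true_pairs.append({"gene1": lo, "gene2": hi, "orthogroup": og, "rediploid_class": cls})
            truth.pair_class[og] = cls
        else:
            truth.negative_cases[og] = mode
            truth.true_singletons.append(g1)
            if mode in ("criterion_i", "criterion_ii", "criterion_iii", "no_synteny"):
                truth.decoy_genes.append(g2)

    return trees, truth


def write_trees(trees: dict[str, str], directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for og in sorted(trees):
        (d / f"{og}.nwk").write_text(trees[og] + "\n")


def species_group_table(config: SimulationConfig) -> pd.DataFrame:
    rows = [(s, "salmonid") for s in config.salmonids]
    rows.append((config.pike, "pike"))
    rows += [(s, "outgroup") for s in config.outgroups]
    return pd.DataFrame(rows, columns=["species", "group"])


# ---------------------------------------------------------------------------
# synteny
# ---------------------------------------------------------------------------

_CLASS_BANDS = {  # percent-identity generator per rediploidization era
    "late": (95.3, 98.5),
    "mid": (90.2, 94.8),
    "early": (85.5, 88.8),
}


def simulate_synteny(config: SimulationConfig, truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the collinear-block and 1-Mbp-window similarity tables.

    Every true pair is covered by one block whose A/B intervals span the
    two loci; window identities are drawn inside the band of the pair's
    assigned class (late >95, mid 90-95, early ~87). Orthogroups flagged
    ``no_synteny`` get no covering block, so they act as synteny-negative
    decoys. Coordinates are 1-based inclusive.
    """

    rng = _rng(config, "synteny")
    blocks, windows = [], []
    for k, rec in enumerate(truth.true_pairs):
        og, cls = rec["orthogroup"], rec["rediploid_class"]
        block_id = f"blk{k:04d}"
        chrom1, s1, _ = truth.loci[rec["gene1"]]
        chrom2, s2, _ = truth.loci[rec["gene2"]]
        a_start = ((s1 - 1) // _BLOCK_SPAN) * _BLOCK_SPAN + 1
        b_start = ((s2 - 1) // _BLOCK_SPAN) * _BLOCK_SPAN + 1
        blocks.append(
            {
                "block_id": block_id,
                "chrA": chrom1,
                "startA": a_start,
                "endA": a_start + _BLOCK_SPAN - 1,
                "chrB": chrom2,
                "startB": b_start,
                "endB": b_start + _BLOCK_SPAN - 1,
            }
        )
        lo, hi = _CLASS_BANDS[cls]
        n_win = _BLOCK_SPAN // 1_000_000
        for w in range(n_win):
            windows.append(
                {
                    "block_id": block_id,
                    "window_index": w + 1,
                    "pct_identity": round(float(rng.uniform(lo, hi)), 3),
                }
            )
    return pd.DataFrame(blocks), pd.DataFrame(windows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

#: sampling schedules of the diel/circadian design (hours; ZT for diel,
#: CT for constant conditions). Diel runs ZT5 through the following ZT5
#: (= hour 29) at 4-h resolution; LL starts at CT9, DD at CT1.
CIRCADIAN_TIMES = {
    "diel": tuple(range(5, 30, 4)),
    "LL": tuple(range(9, 30, 4)),
    "DD": tuple(range(1, 30, 4)),
}

SMOLT_STAGES = ("T1", "T2", "T3", "T4", "T5", "T6")


def archetype_profiles(n_stages: int = 6, n_archetypes: int = 5) -> np.ndarray:
    """Standardized developmental archetype curves (rows sum to mean 0, sd 1).

    Five canonical shapes over the stage axis: monotone rise, monotone
    fall, mid-course peak, mid-course trough, late induction.
    """

    x = np.linspace(0.0, 1.0, n_stages)
    shapes = [
        x,
        -x,
        np.exp(-((x - 0.5) ** 2) / 0.045),
        -np.exp(-((x - 0.5) ** 2) / 0.045),
        1.0 / (1.0 + np.exp(-18 * (x - 0.8))),
    ]
    while len(shapes) < n_archetypes:  # extra archetypes: shifted bumps
        c = 0.2 + 0.6 * (len(shapes) - 4) / max(n_archetypes - 4, 1)
        shapes.append(np.exp(-((x - c) ** 2) / 0.02))
    profiles = np.array(shapes[:n_archetypes])
    profiles -= profiles.mean(axis=1, keepdims=True)
    profiles /= profiles.std(axis=1, keepdims=True)
    return profiles


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 1e-8, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_expression(config: SimulationConfig, truth: GroundTruth) -> ExpressionBundle:
    """Simulate NB counts for the configured design with planted effects.

    Counts are NB(mean = library_size x 2**(baseline + cosine + archetype
    + seawater term), dispersion). Rhythmic genes carry
    ``amplitude * cos(2*pi*(t - phase)/24)`` in the log2 exponent; under
    constant conditions the amplitude is multiplied by the tissue's
    damping factor. Library sizes are drawn log-uniform within 2-fold of
    ``library_size`` to exercise normalization.
    """

    config.validate()
    rng = _rng(config, "expression")
    genes = sorted(truth.gene_universe) or [f"gene{i:04d}" for i in range(config.n_orthogroups)]
    n_genes = len(genes)
    baseline = rng.normal(*config.mean_log2_expression, size=n_genes)

    pair_of: dict[str, tuple[str, str]] = {}
    copy_index: dict[str, int] = {}
    for rec in truth.true_pairs:
        pair_of[rec["gene1"]] = (rec["orthogroup"], rec["gene2"])
        pair_of[rec["gene2"]] = (rec["orthogroup"], rec["gene1"])
        copy_index[rec["gene1"]] = 0
        copy_index[rec["gene2"]] = 1

    design = config.design
    if design == "atlas":
        samples = [
            (f"{t}_r{r + 1}", t, "atlas", "", r + 1)
            for t in config.tissues
            for r in range(config.n_replicates)
        ]
    elif design == "circadian":
        samples = [
            (f"{t}_{cond}_h{h:02d}_r{r + 1}", t, cond, h, r + 1)
            for t in config.tissues
            for cond in ("diel", "LL", "DD")
            for h in CIRCADIAN_TIMES[cond]
            for r in range(config.n_replicates)
        ]
    elif design == "smolt":
        stages = config.timepoints or SMOLT_STAGES
        samples = [
            (f"gill_{st}_r{r + 1}", "gill", "stage", st, r + 1)
            for st in stages
            for r in range(config.n_replicates)
        ]
    elif design == "seawater":
        samples = [
            (f"gill_{cond}_r{r + 1}", "gill", cond, "", r + 1)
            for cond in ("FW", "SW")
            for r in range(config.n_replicates)
        ]
    else:
        raise ValueError(f"unknown design label: {design!r}")

    meta = pd.DataFrame(
        samples, columns=["sample", "tissue", "condition", "time", "replicate"]
    ).set_index("sample")
    n_samples = len(meta)
    log2 = np.tile(baseline[:, None], (1, n_samples))
    gene_idx = {g: i for i, g in enumerate(genes)}

    # ---- planted effects, by design ------------------------------------
    if design == "atlas":
        tissue_effect = rng.normal(0.0, 1.0, size=(n_genes, len(config.tissues)))
        t_col = {t: j for j, t in enumerate(config.tissues)}
        for s, row in enumerate(meta.itertuples()):
            log2[:, s] += tissue_effect[:, t_col[row.tissue]]
        # divergent pairs: copy 2 shifted in a random subset of tissues
        for rec in truth.true_pairs:
            if rng.random() < config.frac_divergent_pairs:
                truth.divergent_pairs.setdefault(rec["orthogroup"], "tissue-shift")
                shift_t = rng.choice(len(config.tissues), size=max(1, len(config.tissues) // 3), replace=False)
                delta = rng.normal(0, 1.5, size=len(shift_t))
                gi = gene_idx[rec["gene2"]]
                for d, tj in zip(delta, shift_t):
                    sel = [s for s, row in enumerate(meta.itertuples()) if t_col[row.tissue] == tj]
                    log2[gi, sel] += d

    # effect assignment is pair-coherent: both copies of a pair share the
    # planted rhythm/archetype/response unless the pair is drawn divergent,
    # so GroundTruth.divergent_pairs is the exact set of differing pairs
    units: list[tuple[str, list[str]]] = [
        (rec["orthogroup"], [rec["gene1"], rec["gene2"]]) for rec in truth.true_pairs
    ] + [("", [g]) for g in truth.true_singletons]
    if not truth.gene_universe:
        units = [("", [g]) for g in genes]

    if design == "circadian":
        damping = {t: config.damping_per_tissue.get(t, 0.5) for t in config.tissues}
        times = meta["time"].to_numpy(dtype=float)
        is_constant = meta["condition"].isin(["LL", "DD"]).to_numpy()
        damp_vec = np.where(is_constant, [damping[t] for t in meta["tissue"]], 1.0)
        for og, members in units:
            if rng.random() >= config.frac_rhythmic:
                continue
            amp = float(rng.lognormal(*config.amplitude_lognormal))
            phase = float(rng.uniform(0.0, 24.0))
            wave = amp * damp_vec * np.cos(2 * np.pi * (times - phase) / 24.0)
            carriers = list(members)
            if len(members) == 2 and rng.random() < config.frac_divergent_pairs:
                carriers = members[:1]  # copy 2 silenced
                truth.divergent_pairs[og] = "one-copy-regulated"
            for g in carriers:
                truth.rhythmic_genes[g] = {
                    "amplitude": amp, "phase_h": phase % 24.0, "damping": dict(damping)
                }
                log2[gene_idx[g]] += wave

    elif design == "smolt":
        stages = list(config.timepoints or SMOLT_STAGES)
        profiles = archetype_profiles(len(stages), config.n_archetypes)
        stage_col = meta["time"].map({st: j for j, st in enumerate(stages)}).to_numpy()
        effect = 1.0  # log2-units multiplier on the sd-1 archetype curve
        for og, members in units:
            if rng.random() >= config.frac_regulated:
                continue
            arch = int(rng.integers(config.n_archetypes))
            assignment = {g: arch for g in members}
            if len(members) == 2 and rng.random() < config.frac_divergent_pairs:
                if rng.random() < 0.5:
                    del assignment[members[1]]  # copy 2 flat
                    truth.divergent_pairs[og] = "one-copy-regulated"
                else:
                    assignment[members[1]] = int(
                        (arch + 1 + rng.integers(config.n_archetypes - 1)) % config.n_archetypes
                    )
                    truth.divergent_pairs[og] = "different-dynamics"
            for g, a in assignment.items():
                truth.archetype_of_gene[g] = a
                log2[gene_idx[g]] += effect * profiles[a][stage_col]

    elif design == "seawater":
        sw = (meta["condition"] == "SW").to_numpy(dtype=float)
        for og, members in units:
            if rng.random() >= config.frac_sw_responsive:
                continue
            fc = float(rng.normal(*config.sw_effect_log2fc))
            carriers = list(members)
            if len(members) == 2 and rng.random() < config.frac_divergent_pairs:
                carriers = members[:1]  # copy 2 unresponsive
                truth.divergent_pairs[og] = "one-copy-regulated"
            for g in carriers:
                truth.sw_responsive[g] = fc
                log2[gene_idx[g]] += fc * sw

    if config.noise_sd_log2 > 0:
        log2 = log2 + rng.normal(0.0, config.noise_sd_log2, size=log2.shape)

    libsizes = config.library_size * 2.0 ** rng.uniform(-1.0, 1.0, size=n_samples)
    mean = (libsizes / 1e6) * 2.0**log2
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index, dtype=np.int64)
    counts_df.index.name = "gene"
    return ExpressionBundle(
        counts=counts_df, meta=meta,
        true_library_sizes=pd.Series(libsizes, index=meta.index),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.true_pairs).to_csv(d / "true_pairs.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": truth.true_singletons}).to_csv(d / "true_singletons.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(og, m) for og, m in sorted(truth.negative_cases.items())],
        columns=["orthogroup", "violation"],
    ).to_csv(d / "negative_cases.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, v["amplitude"], v["phase_h"]) for g, v in sorted(truth.rhythmic_genes.items())],
        columns=["gene", "amplitude", "phase_h"],
    ).to_csv(d / "rhythmic_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, a) for g, a in sorted(truth.archetype_of_gene.items())],
        columns=["gene", "archetype"],
    ).to_csv(d / "archetypes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, fc) for g, fc in sorted(truth.sw_responsive.items())],
        columns=["gene", "log2fc"],
    ).to_csv(d / "sw_responsive.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(p, m) for p, m in sorted(truth.divergent_pairs.items())],
        columns=["pair", "mode"],
    ).to_csv(d / "divergent_pairs.tsv", sep="\t", index=False)
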