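"""Forward simulator for the paired hatchery-line study design.

The generator emulates a supportive-breeding programme: a wild founder
population (``P1``) gives rise to two hatchery lines propagated in parallel
for ``n_generations``.  The segregated line (``SEG``) is a closed
Wright-Fisher population of effective size ``ne_segregated``; loci under
domestication selection experience viability selection there with
multiplicative fitnesses (1, 1+s/2, 1+s).  The integrated line (``INT``)
draws a fraction ``gene_flow_integrated`` of its parents each generation
from a persistent wild pool (size ``ne_wild``) that itself drifts from the
founder frequencies; with the default fraction of 1.0 the integrated
broodstock is entirely wild-born each generation, which is how managed gene
flow operates in the programme being emulated.

Loci are unlinked: each population is propagated per locus by binomial
sampling of 2*Ne gametes, and sampled individuals are drawn
Hardy-Weinberg from the current line frequencies.  Selection on a
chromosome *block* is modelled by giving every locus in the block its own
selection coefficient, so linkage is not needed for region-level power.

Phenotypes are additive-polygenic with line/sex/year confounding; read
depths are negative-binomial with a binomial allele split; proxy-genome
alignments are constructed with known ground truth so the map-anchoring
step can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hatchscan.config import SimConfig
from hatchscan.containers import GenotypeMatrix, TRAITS, population_label

# stage keys ensure each operation gets an independent, reproducible stream
_STAGE = {"map": 1, "founders": 2, "propagate": 3, "pheno": 4, "depth": 5, "align": 6}


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], config.seed])


@dataclass
class Population:
    """One sampled population: a line at a generation.

    ``freqs`` holds the *true* line allele frequencies at this generation
    (the drift state), from which the sampled genotypes were drawn; keeping
    them on the object records the full frequency trajectory across the
    returned population list.
    """

    line: str
    generation: int
    dosages: pd.DataFrame  # individuals x loci, values 0/1/2
    sexes: pd.Series  # per individual, "F"/"M"
    freqs: pd.Series  # per locus true allele frequency

    @property
    def label(self) -> str:
        return population_label(self.line, self.generation)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        samples = pd.DataFrame(
            {
                "line": self.line,
                "generation": self.generation,
                "sex": self.sexes,
            },
            index=self.dosages.index,
        )
        return GenotypeMatrix(self.dosages.copy(), samples)


def simulate_linkage_map(config: SimConfig) -> pd.DataFrame:
    """Assign loci uniformly to chromosomes with uniform cM positions.

    A fraction ``mapped_fraction`` of loci is flagged as present on the
    linkage map; the rest are "unmapped" and exercise the anchoring step.
    Returns columns ``locus, chromosome, cM, mapped``.
    """
    rng = _rng(config, "map")
    loci = [f"L{i:05d}" for i in range(config.n_loci)]
    chrom = rng.integers(1, config.n_chromosomes + 1, size=config.n_loci)
    cm = rng.uniform(0.0, 100.0, size=config.n_loci)
    mapped = rng.random(config.n_loci) < config.mapped_fraction
    return pd.DataFrame(
        {"locus": loci, "chromosome": chrom, "cM": cm, "mapped": mapped}
    )


def simulate_founders(config: SimConfig) -> Population:
    """Draw founder allele frequencies and Hardy-Weinberg genotypes.

    Frequencies come from the Beta distribution ``founder_maf_dist``; they
    are the true founder-population frequencies from which both the founder
    genotype sample and the line trajectories descend.
    """
    rng = _rng(config, "founders")
    loci = [f"L{i:05d}" for i in range(config.n_loci)]
    a, b = config.founder_maf_dist
    p = rng.beta(a, b, size=config.n_loci)
    n = config.n_founders
    dos = rng.binomial(2, p, size=(n, config.n_loci)).astype(float)
    ids = [f"P1_F0_{i:04d}" for i in range(n)]
    sexes = pd.Series(np.where(rng.random(n) < 0.5, "F", "M"), index=ids)
    dosages = pd.DataFrame(dos, index=ids, columns=loci)
    return Population("P1", 0, dosages, sexes, pd.Series(p, index=loci))


def _selection_shift(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Post-viability-selection allele frequency for fitnesses (1, 1+s/2, 1+s)."""
    q = 1.0 - p
    num = p * p * (1.0 + s) + p * q * (1.0 + s / 2.0)
    wbar = p * p * (1.0 + s) + 2.0 * p * q * (1.0 + s / 2.0) + q * q
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wbar > 0, num / wbar, p)
    return out


def propagate_lines(founders: Population, config: SimConfig) -> list[Population]:
    """Propagate both hatchery lines F1..Fn from the founder sample.

    Returns populations ordered [INT_F1..INT_Fn, SEG_F1..SEG_Fn].  Loci may
    fix in either line; fixation is benign.  Selection (``selected_loci``)
    acts in the segregated line only.
    """
    rng = _rng(config, "propagate")
    loci = founders.dosages.columns
    # base frequencies: the true founder-population frequencies; the founder
    # genotypes are a sample of these, so temporal comparisons carry
    # sampling noise at both ends, as the drift null assumes
    p0 = founders.freqs.to_numpy().copy()

    s = np.zeros(len(loci))
    if config.selected_loci:
        idx = {loc: i for i, loc in enumerate(loci)}
        for loc, coef in config.selected_loci:
            if loc in idx:
                s[idx[loc]] = coef

    p_wild = p0.copy()
    p_int = p0.copy()
    p_seg = p0.copy()
    ne_w, ne_i, ne_s = config.ne_wild, config.ne_integrated, config.ne_segregated
    m = config.gene_flow_integrated

    pops: list[Population] = []
    int_pops: list[Population] = []
    seg_pops: list[Population] = []
    for gen in range(1, config.n_generations + 1):
        p_wild = rng.binomial(2 * ne_w, p_wild) / (2.0 * ne_w)
        parental_int = (1.0 - m) * p_int + m * p_wild
        p_int = rng.binomial(2 * ne_i, parental_int) / (2.0 * ne_i)
        p_seg_sel = _selection_shift(p_seg, s)
        p_seg = rng.binomial(2 * ne_s, p_seg_sel) / (2.0 * ne_s)

        for line, p in (("INT", p_int), ("SEG", p_seg)):
            n = config.samples_per_population
            dos = rng.binomial(2, p, size=(n, len(loci))).astype(float)
            ids = [f"{line}_F{gen}_{i:04d}" for i in range(n)]
            sexes = pd.Series(np.where(rng.random(n) < 0.5, "F", "M"), index=ids)
            pop = Population(
                line,
                gen,
                pd.DataFrame(dos, index=ids, columns=loci),
                sexes,
                pd.Series(p.copy(), index=loci),
            )
            (int_pops if line == "INT" else seg_pops).append(pop)
    pops = int_pops + seg_pops
    return pops


def combine_populations(populations: list[Population]) -> GenotypeMatrix:
    """Stack sampled populations into one genotype matrix with labels."""
    dos = pd.concat([p.dosages for p in populations], axis=0)
    samples = pd.concat(
        [
            pd.DataFrame(
                {"line": p.line, "generation": p.generation, "sex": p.sexes},
                index=p.dosages.index,
            )
            for p in populations
        ]
    )
    return GenotypeMatrix(dos, samples)


# ---------------------------------------------------------------------------
# phenotypes

_TRAIT_SCALE = {
    # trait -> (location, scale) on the observed scale, from the study system:
    # returns peak mid-June (~day 157), spawning late September (~day 266),
    # adult fork length ~72 cm, daily growth coefficient slightly negative
    # because adults lose weight during hatchery holding.
    "return_day": (157.0, 8.0),
    "spawn_day": (266.0, 7.0),
    "length_cm": (72.0, 5.0),
    "dgc": (-0.05, 0.015),
}


def simulate_phenotypes(
    populations: list[Population],
    config: SimConfig,
    causal_loci: dict[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Simulate the six fitness traits for all sampled individuals.

    Each trait is additive over its causal loci plus line/sex/year fixed
    effects plus Gaussian noise scaled so the realized heritability matches
    the target.  ``age`` is ordinal {3,4,5}, obtained by thresholding the
    latent continuous value at its 12.5% and 87.5% quantiles so roughly 75%
    of adults mature at age four.  ``weight_kg`` is allometric:
    log(weight) = log(a) + 3*log(fork length) + latent weight deviation.

    Returns the phenotype table and the per-trait causal-effect vectors
    (pd.Series indexed by causal locus) used, which are the ground truth for
    association power checks.  Pass ``causal_loci`` to pin architectures
    (e.g. for pleiotropy scenarios); otherwise causal loci are drawn at
    random per trait.
    """
    rng = _rng(config, "pheno")
    gm = combine_populations(populations)
    dos = gm.dosages.to_numpy()
    n = dos.shape[0]
    loci = gm.dosages.columns

    line = gm.samples["line"].to_numpy()
    gen = gm.samples["generation"].to_numpy()
    sex = gm.samples["sex"].to_numpy()
    is_seg = (line == "SEG").astype(float)
    is_male = (sex == "M").astype(float)

    effects: dict[str, pd.Series] = {}
    latent: dict[str, np.ndarray] = {}
    for trait in TRAITS:
        arch = config.trait_architectures[trait]
        if causal_loci is not None and trait in causal_loci:
            eff = causal_loci[trait].astype(float)
        else:
            freq = dos.mean(axis=0) / 2.0
            maf = np.minimum(freq, 1.0 - freq)
            eligible = np.where(maf >= arch.min_causal_maf)[0]
            if len(eligible) < arch.n_causal:
                eligible = np.arange(len(loci))
            chosen = rng.choice(eligible, size=min(arch.n_causal, len(eligible)), replace=False)
            if arch.effect_kind == "standardized":
                sd = dos[:, chosen].std(axis=0)
                sd[sd == 0] = 1.0
                signs = np.where(rng.random(len(chosen)) < 0.5, -1.0, 1.0)
                vals = signs * arch.effect_sd / sd
            else:
                vals = rng.normal(0.0, arch.effect_sd, size=len(chosen))
            eff = pd.Series(vals, index=loci[chosen])
        effects[trait] = eff

        if arch.h2 > 0 and len(eff) > 0:
            g = dos[:, [loci.get_loc(l) for l in eff.index]] @ eff.to_numpy()
            var_g = float(np.var(g))
            if var_g == 0.0:
                g = np.zeros(n)
                sigma_e = 1.0
            else:
                sigma_e = np.sqrt(var_g * (1.0 - arch.h2) / arch.h2)
        else:
            g = np.zeros(n)
            sigma_e = 1.0
        y = (
            g
            + arch.line_effect * is_seg
            + arch.sex_effect * is_male
            + arch.year_effect * gen
            + rng.normal(0.0, sigma_e, size=n)
        )
        latent[trait] = y

    def standardize(y: np.ndarray) -> np.ndarray:
        sd = y.std()
        return (y - y.mean()) / (sd if sd > 0 else 1.0)

    table = pd.DataFrame(index=gm.dosages.index)
    table["line"] = line
    table["generation"] = gen
    table["sex"] = sex
    table["year"] = 1998 + 4 * gen  # founders 1998; hatchery broods every 4 years

    z_age = standardize(latent["age"])
    lo, hi = np.quantile(z_age, [0.125, 0.875])
    table["age"] = np.where(z_age < lo, 3, np.where(z_age >= hi, 5, 4))

    for trait in ("return_day", "spawn_day", "length_cm", "dgc"):
        loc, scale = _TRAIT_SCALE[trait]
        table[trait] = loc + scale * standardize(latent[trait])
    table["length_cm"] = table["length_cm"].clip(lower=30.0)

    # weight: allometric in fork length plus the weight trait's latent value
    # (2% residual CV of weight at length, within-age adults)
    z_w = standardize(latent["weight_kg"])
    table["weight_kg"] = np.exp(
        np.log(1.28e-5) + 3.0 * np.log(table["length_cm"]) + 0.02 * z_w
    )

    # holding-period bookkeeping consistent with the daily growth coefficient
    days = rng.integers(40, 81, size=n)
    table["holding_days"] = days
    table["initial_weight_kg"] = table["weight_kg"]
    root = np.cbrt(table["initial_weight_kg"].to_numpy()) + table[
        "dgc"
    ].to_numpy() * days / 100.0
    table["final_weight_kg"] = np.maximum(root, 0.05) ** 3

    table.index.name = "individual"
    return table, effects


# ---------------------------------------------------------------------------
# read depths


def simulate_depths(populations: list[Population], config: SimConfig) -> pd.DataFrame:
    """Simulate per-allele RAD read depths for every (individual, locus).

    Total depth ~ NegBin(mean, dispersion); heterozygotes split reads
    Binomial(total, 0.5), homozygotes put Binomial(total, error_rate) reads
    on the absent allele.  Returns a long-form table with columns
    ``individual, locus, depth_a1, depth_a2`` where allele 1 is the
    reference (dosage counts copies of allele 2).
    """
    rng = _rng(config, "depth")
    gm = combine_populations(populations)
    dos = gm.dosages.to_numpy()
    n_ind, n_loc = dos.shape
    dm = config.depth_model

    k = dm.dispersion
    p_nb = k / (k + dm.mean_depth)
    total = rng.negative_binomial(k, p_nb, size=(n_ind, n_loc))

    d2 = np.empty_like(total)
    het = dos == 1
    hom_ref = dos == 0
    hom_alt = dos == 2
    d2[het] = rng.binomial(total[het], 0.5)
    d2[hom_ref] = rng.binomial(total[hom_ref], dm.error_rate)
    off1 = rng.binomial(total[hom_alt], dm.error_rate)
    d2[hom_alt] = total[hom_alt] - off1
    d1 = total - d2

    out = pd.DataFrame(
        {
            "individual": np.repeat(gm.dosages.index.to_numpy(), n_loc),
            "locus": np.tile(gm.dosages.columns.to_numpy(), n_ind),
            "depth_a1": d1.ravel(),
            "depth_a2": d2.ravel(),
        }
    )
    return out


def domestication_scenario(
    seed: int,
    n_loci: int = 500,
    samples_per_population: int = 100,
    n_founders: int = 100,
    trait: str = "spawn_day",
    n_causal: int = 10,
    h2: float = 0.5,
    s: float = 0.5,
    mapped_fraction: float = 1.0,
    with_depths: bool = False,
    with_alignments: bool = False,
) -> SimStudy:
    """Study with domestication selection on one trait's causal loci.

    Emulates the hypothesis the paired-line design tests: loci underlying a
    fitness trait (spawn timing by default) respond to hatchery selection in
    the segregated line only.  Causal loci are pinned to mid-frequency
    founder loci (so power is comparable across them), given equal
    standardized effects with random sign, and each receives selection
    coefficient ``s`` in the segregated line.
    """
    from hatchscan.config import TraitArchitecture

    cfg0 = SimConfig(
        n_loci=n_loci,
        samples_per_population=samples_per_population,
        n_founders=n_founders,
        mapped_fraction=mapped_fraction,
        seed=seed,
    )
    founders = simulate_founders(cfg0)
    p = founders.freqs
    rng = np.random.default_rng([9, seed])
    mid = p.index[(p > 0.2) & (p < 0.8)]
    if len(mid) < n_causal:
        mid = p.index
    chosen = list(rng.choice(mid, size=n_causal, replace=False))
    signs = np.where(rng.random(n_causal) < 0.5, -1.0, 1.0)
    sd = np.sqrt(2.0 * p[chosen] * (1.0 - p[chosen])).to_numpy()
    effects = pd.Series(signs / np.maximum(sd, 1e-6), index=chosen)

    arch = {t: TraitArchitecture() for t in TRAITS}
    arch[trait] = TraitArchitecture(n_causal=n_causal, h2=h2)
    cfg = SimConfig(
        n_loci=n_loci,
        samples_per_population=samples_per_population,
        n_founders=n_founders,
        mapped_fraction=mapped_fraction,
        selected_loci=[(l, s) for l in chosen],
        trait_architectures=arch,
        seed=seed,
    )
    return simulate_study(
        cfg,
        with_depths=with_depths,
        with_alignments=with_alignments,
        causal_loci={trait: effects},
    )


def place_loci(
    linkage_map: pd.DataFrame,
    loci: list[str],
    chromosome: int,
    start_cM: float,
    end_cM: float,
) -> pd.DataFrame:
    """Reposition ``loci`` evenly across a map interval (scenario builder).

    Loci are unlinked in the simulator, so map positions are free scenario
    parameters; this is how a dense block of selected loci is planted on a
    chromosome for region-level power studies.  Returns a modified copy.
    """
    lm = linkage_map.copy()
    idx = lm["locus"].isin(loci)
    k = int(idx.sum())
    if k == 0:
        return lm
    lm.loc[idx, "chromosome"] = chromosome
    lm.loc[idx, "cM"] = np.linspace(start_cM, end_cM, k)
    lm.loc[idx, "mapped"] = True
    return lm


# ---------------------------------------------------------------------------
# proxy-genome alignments


def simulate_alignments(
    linkage_map: pd.DataFrame,
    config: SimConfig,
    *,
    genome: str = "rainbow_trout",
    align_fraction: float = 0.8,
    frac_far: float = 0.15,
    frac_lowq: float = 0.1,
    near_range: tuple[int, int] = (5_000, 80_000),
    far_range: tuple[int, int] = (120_000, 200_000),
    mapq_good: int = 42,
    mapq_bad: int = 5,
    locus_len: int = 74,
    stage_offset: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct proxy-genome alignments with known anchoring ground truth.

    Every mapped locus is placed on its own contig; each aligned unmapped
    locus is placed on the contig of a randomly chosen mapped "donor" locus
    at a controlled gap distance, so the nearest mapped locus is the donor
    by construction.  A fraction ``frac_far`` of unmapped loci is planted
    beyond the recovery distance and ``frac_lowq`` below the mapping-quality
    floor; these must *not* be recovered.

    Returns ``(alignments, truth)``: BED-like records (0-based half-open
    ``contig, start, end, locus, mapq, genome``) and a truth table with the
    intended donor, gap distance, mapq and a ``recoverable`` flag (distance
    <= 100 kb and both mapq >= 10).
    """
    rng = np.random.default_rng([_STAGE["align"] + stage_offset, config.seed])
    mapped = linkage_map[linkage_map["mapped"]].reset_index(drop=True)
    unmapped = linkage_map[~linkage_map["mapped"]].reset_index(drop=True)
    if mapped.empty:
        raise ValueError("linkage map contains no mapped loci")

    base = 1_000_000
    records = []
    for _, row in mapped.iterrows():
        records.append(
            {
                "contig": f"{genome}_ctg_{row.locus}",
                "start": base,
                "end": base + locus_len,
                "locus": row.locus,
                "mapq": mapq_good,
                "genome": genome,
            }
        )

    truth_rows = []
    aligned = unmapped[rng.random(len(unmapped)) < align_fraction]
    for _, row in aligned.iterrows():
        donor = mapped.iloc[int(rng.integers(len(mapped)))]
        u = rng.random()
        if u < frac_far:
            gap = int(rng.integers(*far_range))
            mq = mapq_good
        elif u < frac_far + frac_lowq:
            gap = int(rng.integers(*near_range))
            mq = mapq_bad
        else:
            gap = int(rng.integers(*near_range))
            mq = mapq_good
        start = base + locus_len + gap
        records.append(
            {
                "contig": f"{genome}_ctg_{donor.locus}",
                "start": start,
                "end": start + locus_len,
                "locus": row.locus,
                "mapq": mq,
                "genome": genome,
            }
        )
        truth_rows.append(
            {
                "locus": row.locus,
                "donor": donor.locus,
                "genome": genome,
                "distance": gap,
                "mapq": mq,
                "recoverable": (gap <= 100_000) and (mq >= 10),
                "chromosome": donor.chromosome,
                "cM": donor.cM,
            }
        )

    alignments = pd.DataFrame(records)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "locus",
            "donor",
            "genome",
            "distance",
            "mapq",
            "recoverable",
            "chromosome",
            "cM",
        ],
    )
    return alignments, truth


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimStudy:
    """Bundle of everything one simulated study emits."""

    config: SimConfig
    founders: Population
    populations: list[Population]  # hatchery lines, founders excluded
    genotypes: GenotypeMatrix  # founders + both lines
    linkage_map: pd.DataFrame
    phenotypes: pd.DataFrame
    causal_effects: dict[str, pd.Series]
    depths: pd.DataFrame | None = None
    alignments: pd.DataFrame | None = None
    alignment_truth: pd.DataFrame | None = None
    trajectories: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_study(
    config: SimConfig,
    *,
    with_depths: bool = False,
    with_alignments: bool = False,
    causal_loci: dict[str, pd.Series] | None = None,
) -> SimStudy:
    """Run the full generator: founders, lines, phenotypes, optional extras."""
    founders = simulate_founders(config)
    pops = propagate_lines(founders, config)
    all_pops = [founders] + pops
    gm = combine_populations(all_pops)
    linkage_map = simulate_linkage_map(config)
    pheno, effects = simulate_phenotypes(all_pops, config, causal_loci=causal_loci)

    traj: dict[str, np.ndarray] = {}
    for line in ("INT", "SEG"):
        rows = [founders.freqs.to_numpy()] + [
            p.freqs.to_numpy() for p in pops if p.line == line
        ]
        traj[line] = np.vstack(rows)

    study = SimStudy(
        config=config,
        founders=founders,
        populations=pops,
        genotypes=gm,
        linkage_map=linkage_map,
        phenotypes=pheno,
        causal_effects=effects,
        trajectories=traj,
    )
    if with_depths:
        study.depths = simulate_depths(all_pops, config)
    if with_alignments:
        study.alignments, study.alignment_truth = simulate_alignments(
            linkage_map, config
        )
    return study
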