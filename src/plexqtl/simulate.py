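"""Synthetic autotetraploid F1 bulked-segregant datasets.

Simulates the full experimental design this package analyzes: two
tetraploid parents carrying simplex/duplex variants on known homologs,
F1 meiosis (random bivalent pairing, Poisson crossovers, no double
reduction), dosage-driven phenotypes, phenotype-tail bulks, and binomial
read sampling — emitted as a multi-sample VCF plus truth tables, so the
whole pipeline is testable without any external data.

Meiosis model: per chromosome the four homologs pair at random into two
bivalents each meiosis; each bivalent receives a Poisson number of
crossovers (mean = genetic length in Morgans; Haldane, no interference)
at uniform positions, and contributes one recombinant chromatid to the
gamete.  Two bivalents -> two chromatids -> a balanced 2n gamete.  Double
reduction is absent, so marginal gamete dosages are exactly the
hypergeometric law in :mod:`plexqtl.genetics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import CrossSpec, progeny_dosage_distribution

PLOIDY = 4  # autotetraploid throughout; gametes carry PLOIDY // 2 homologs

_BASES = np.array(list("ACGT"))


class EmptyDatasetError(ValueError):
    """Raised when a simulation request yields no variants or individuals."""


@dataclass(frozen=True)
class GenomeSpec:
    """Synthetic genome coordinates and rates.

    chromosomes: (name, length in bp) pairs.
    recomb_rate: constant recombination rate in cM/Mb.
    variant_density: expected variants per bp (all classes pooled).
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr01", 10_000_000),)
    recomb_rate: float = 4.0
    variant_density: float = 1e-3

    def __post_init__(self) -> None:
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recombination rate must be >= 0")
        if self.variant_density <= 0:
            raise ValueError("variant density must be positive")

    def morgans(self, length_bp: int) -> float:
        """Genetic length of a segment: bp * (cM/Mb) / 1e8."""
        return length_bp * self.recomb_rate / 1e8


@dataclass(frozen=True)
class SimVariant:
    """One planted variant: its donor parent and the homologs carrying ALT."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    donor: str  # "P1" | "P2"
    plexity: int  # |carriers|
    carriers: tuple[int, ...]  # homolog indices (0..3) of the donor

    def __post_init__(self) -> None:
        if len(self.carriers) != self.plexity:
            raise ValueError("carrier set size must equal plexity")


@dataclass
class Parents:
    """Two parental 4-haplotype genomes described by their variant carriers.

    ``carriers[parent]`` is an (n_variants, 4) boolean matrix; homolog ``h``
    of ``parent`` carries variant ``i`` iff ``carriers[parent][i, h]``.
    The non-donor parent is nulliplex at every variant by construction.
    """

    genome: GenomeSpec
    variants: list[SimVariant]
    carriers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.carriers:
            n = len(self.variants)
            self.carriers = {p: np.zeros((n, PLOIDY), dtype=bool) for p in ("P1", "P2")}
            for i, v in enumerate(self.variants):
                self.carriers[v.donor][i, list(v.carriers)] = True

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "donor": [v.donor for v in self.variants],
                "plexity": [v.plexity for v in self.variants],
            }
        )


def _normalize_plexity_mix(plexity_mix: dict) -> dict[int, float]:
    mix = {}
    for key, frac in plexity_mix.items():
        m = {"simplex": 1, "duplex": 2}.get(key, key)
        if m not in (1, 2):
            raise ValueError(f"plexity mix keys must be simplex/duplex (1/2), got {key!r}")
        if frac < 0:
            raise ValueError("plexity fractions must be >= 0")
        mix[int(m)] = mix.get(int(m), 0.0) + float(frac)
    total = sum(mix.values())
    if not 0 < total <= 1 + 1e-9:
        raise ValueError("plexity fractions must be in (0, 1] in total")
    return {m: f / total for m, f in mix.items()}


def simulate_parents(
    genome: GenomeSpec,
    plexity_mix: dict | None = None,
    seed: int | None = None,
    donor_fraction_p1: float = 0.5,
    duplex_phase: str = "coherent",
) -> Parents:
    """Plant variants on the parental homologs.

    Variant counts per chromosome are Poisson(density * length) with unique
    uniform positions.  Each variant is assigned a donor parent (P1 with
    probability ``donor_fraction_p1``) and a plexity drawn from
    ``plexity_mix`` (default 80% simplex / 20% duplex, roughly the
    simplex:duplex proportion seen in tetraploid potato crosses).

    Simplex carriers are uniform over the four homologs: each homolog
    accumulates its own private variants along its length.  Duplex
    carriers follow ``duplex_phase``:

    * ``"coherent"`` (default) — per parent and chromosome one homolog
      pair is drawn and every duplex variant sits on it, modeling the
      local identity-by-descent of two homologs that makes real duplex
      variants in a region phase-coherent (and a directional ΔSNP-index
      excess detectable);
    * ``"random"`` — an independent uniform pair per variant.
    """
    mix = _normalize_plexity_mix(plexity_mix or {1: 0.8, 2: 0.2})
    if duplex_phase not in ("coherent", "random"):
        raise ValueError("duplex_phase must be 'coherent' or 'random'")
    rng = np.random.default_rng(seed)
    plexities = np.array(sorted(mix))
    plex_probs = np.array([mix[m] for m in plexities], dtype=float)

    variants: list[SimVariant] = []
    for chrom, length in genome.chromosomes:
        duplex_pair = {
            parent: tuple(sorted(rng.choice(PLOIDY, size=2, replace=False)))
            for parent in ("P1", "P2")
        }
        n = rng.poisson(genome.variant_density * length)
        n = min(n, length)
        if n == 0:
            continue
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        refs = _BASES[rng.integers(0, 4, size=n)]
        alts = _BASES[(np.char.index("ACGT", refs) + rng.integers(1, 4, size=n)) % 4]
        donors = np.where(rng.random(n) < donor_fraction_p1, "P1", "P2")
        ms = plexities[rng.choice(len(plexities), size=n, p=plex_probs)]
        for p, r, a, d, m in zip(pos, refs, alts, donors, ms):
            if m == 2 and duplex_phase == "coherent":
                carriers = duplex_pair[str(d)]
            else:
                carriers = tuple(sorted(rng.choice(PLOIDY, size=int(m), replace=False)))
            variants.append(SimVariant(chrom, int(p), str(r), str(a), str(d), int(m), carriers))
    if not variants:
        raise EmptyDatasetError("no variants generated; increase density or genome size")
    return Parents(genome, variants)


@dataclass
class Chromatid:
    """A recombinant chromatid as homolog-ancestry segments.

    ``origins[i]`` is the parental homolog (0..3) between ``breaks[i-1]``
    and ``breaks[i]`` (1-based positions; breaks sorted, len(origins) =
    len(breaks) + 1).
    """

    breaks: np.ndarray
    origins: np.ndarray

    def origin_at(self, pos: np.ndarray) -> np.ndarray:
        return self.origins[np.searchsorted(self.breaks, pos, side="right")]


def make_gamete(
    genome: GenomeSpec, rng: np.random.Generator
) -> dict[str, list[Chromatid]]:
    """One balanced 2n gamete: two recombinant chromatids per chromosome.

    Homologs 0..3 pair into two random bivalents; each bivalent undergoes
    Poisson(Morgans) crossovers at uniform positions and yields one
    chromatid that alternates between its two homologs at the crossover
    points, starting from a random one.
    """
    gamete: dict[str, list[Chromatid]] = {}
    for chrom, length in genome.chromosomes:
        pairing = rng.permutation(PLOIDY)
        bivalents = [pairing[:2], pairing[2:]]
        chromatids = []
        for pair in bivalents:
            n_co = rng.poisson(genome.morgans(length))
            breaks = np.sort(rng.uniform(0, length, size=n_co))
            start = rng.integers(0, 2)
            origins = pair[(start + np.arange(n_co + 1)) % 2]
            chromatids.append(Chromatid(breaks, origins))
        gamete[chrom] = chromatids
    return gamete


def _gamete_dosages(
    gamete: dict[str, list[Chromatid]],
    carriers: np.ndarray,
    pos_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """ALT copies contributed by one gamete at every variant (row) index."""
    dosage = np.zeros(carriers.shape[0], dtype=np.int8)
    for chrom, (rows, pos) in pos_by_chrom.items():
        for chromatid in gamete[chrom]:
            homologs = chromatid.origin_at(pos)
            dosage[rows] += carriers[rows, homologs]
    return dosage


@dataclass
class Population:
    """An F1 population: per-variant ALT dosage of every individual."""

    parents: Parents
    dosages: np.ndarray  # (n_variants, n_individuals) int8, 0..4

    @property
    def size(self) -> int:
        return self.dosages.shape[1]


def simulate_population(parents: Parents, n: int, seed: int | None = None) -> Population:
    """Cross the two parents n times; each progeny unites one gamete from each."""
    if n < 1:
        raise EmptyDatasetError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    frame = parents.variant_frame()
    pos_by_chrom = {
        chrom: (grp.index.to_numpy(), grp["pos"].to_numpy(float))
        for chrom, grp in frame.groupby("chrom", sort=True)
    }
    dosages = np.zeros((len(parents.variants), n), dtype=np.int8)
    for j in range(n):
        for parent in ("P1", "P2"):
            gamete = make_gamete(parents.genome, rng)
            dosages[:, j] += _gamete_dosages(gamete, parents.carriers[parent], pos_by_chrom)
    return Population(parents, dosages)


def chroma(a_star: float, b_star: float) -> float:
    """CIE 1976 chroma C* = sqrt(a*^2 + b*^2) — the yellow-flesh intensity score."""
    return math.hypot(a_star, b_star)


@dataclass(frozen=True)
class QtlModel:
    """A single causal locus acting on a quantitative phenotype.

    additive: value = baseline + effect * dosage + N(0, sd) — the
    dosage-dependent pattern of a starch-phosphorus-like trait.
    dominant: value = baseline + effect * 1{dosage >= 1} + N(0, sd) — the
    presence/absence pattern of a flesh-color-like trait.
    """

    causal_index: int
    mode: str = "additive"
    effect: float = 1.0
    noise_sd: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "dominant"):
            raise ValueError("mode must be 'additive' or 'dominant'")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def assign_phenotypes(
    population: Population, qtl: QtlModel, seed: int | None = None
) -> np.ndarray:
    """Phenotype per individual from the causal variant's dosage plus noise."""
    if not 0 <= qtl.causal_index < population.dosages.shape[0]:
        raise ValueError("causal variant index out of range")
    dosage = population.dosages[qtl.causal_index].astype(float)
    rng = np.random.default_rng(seed)
    genetic = dosage if qtl.mode == "additive" else (dosage >= 1).astype(float)
    return qtl.baseline + qtl.effect * genetic + rng.normal(0.0, qtl.noise_sd, population.size)


@dataclass(frozen=True)
class BulkSpec:
    """Tail-bulk selection: fixed sizes per tail, or phenotype cutoffs."""

    n_low: int | None = None
    n_high: int | None = None
    low_cutoff: float | None = None
    high_cutoff: float | None = None

    def __post_init__(self) -> None:
        by_size = self.n_low is not None and self.n_high is not None
        by_cut = self.low_cutoff is not None and self.high_cutoff is not None
        if not (by_size or by_cut):
            raise ValueError("provide bulk sizes or phenotype cutoffs")
        if by_size and (self.n_low < 1 or self.n_high < 1):
            raise ValueError("bulk sizes must be >= 1")
        if by_cut and not by_size and self.low_cutoff >= self.high_cutoff:
            raise ValueError("low cutoff must be below high cutoff")


def bulk_fraction_percent(n_selected: int, n_population: int) -> float:
    """Bulk size as percent of the phenotyped population, one decimal (19/169 -> 11.2)."""
    return round(100.0 * n_selected / n_population, 1)


def select_bulks(
    phenotypes: np.ndarray, spec: BulkSpec
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Pick the two phenotype tails.

    Returns (low-tail indices, high-tail indices, their percent fractions of
    the population).  Size-based selection takes the n lowest / n highest
    values (ties broken by index); cutoff-based takes values strictly below
    / above the cutoffs.  The tails must be disjoint and non-empty.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    n = len(phenotypes)
    if spec.n_low is not None:
        if spec.n_low + spec.n_high > n:
            raise ValueError("tails overlap: bulk sizes exceed the population")
        order = np.argsort(phenotypes, kind="stable")
        low = np.sort(order[: spec.n_low])
        high = np.sort(order[n - spec.n_high:])
    else:
        low = np.flatnonzero(phenotypes < spec.low_cutoff)
        high = np.flatnonzero(phenotypes > spec.high_cutoff)
        if np.intersect1d(low, high).size:
            raise ValueError("cutoffs select overlapping tails")
    if low.size == 0 or high.size == 0:
        raise EmptyDatasetError("a selection tail is empty")
    return low, high, (bulk_fraction_percent(low.size, n), bulk_fraction_percent(high.size, n))


@dataclass(frozen=True)
class ReadDepthModel:
    """Per-sample sequencing depth and error: fixed or Poisson depth law."""

    mean_depth: float = 60.0
    depth_law: str = "fixed"
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth < 1:
            raise ValueError("mean depth must be >= 1")
        if self.depth_law not in ("fixed", "poisson"):
            raise ValueError("depth law must be 'fixed' or 'poisson'")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")


def sample_reads(
    alt_fractions: np.ndarray,
    depth_model: ReadDepthModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial read counts at each variant given true pooled ALT fractions.

    ALT reads ~ Binomial(d, f*(1-e) + (1-f)*e): each of d reads samples a
    chromosome copy from the pool and miscalls with probability e.
    Returns (REF depths, ALT depths).
    """
    f = np.asarray(alt_fractions, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("allele fractions must lie in [0, 1]")
    if depth_model.depth_law == "fixed":
        depths = np.full(f.shape, int(round(depth_model.mean_depth)))
    else:
        depths = rng.poisson(depth_model.mean_depth, size=f.shape)
    e = depth_model.error_rate
    p = f * (1 - e) + (1 - f) * e
    alt = rng.binomial(depths, p)
    return depths - alt, alt


def bulk_allele_fractions(population: Population, individuals: np.ndarray) -> np.ndarray:
    """True pooled ALT fraction per variant for a bulk of individuals."""
    individuals = np.asarray(individuals)
    if individuals.size == 0:
        raise EmptyDatasetError("empty individual set")
    return population.dosages[:, individuals].sum(axis=1) / (PLOIDY * individuals.size)


def parent_allele_fractions(parents: Parents, parent: str) -> np.ndarray:
    """True ALT fraction per variant in one parent (m/4 for its own variants)."""
    return parents.carriers[parent].sum(axis=1) / PLOIDY


@dataclass
class BsaDataset:
    """A complete simulated experiment plus its truth."""

    parents: Parents
    population: Population
    phenotypes: np.ndarray
    low_bulk: np.ndarray
    high_bulk: np.ndarray
    bulk_fractions: tuple[float, float]
    observations: pd.DataFrame  # read-depth table consumed by plexqtl.core
    qtl: QtlModel


def simulate_bsa_dataset(
    genome: GenomeSpec,
    qtl_mode: str = "additive",
    qtl_donor: str = "P2",
    qtl_plexity: int = 2,
    effect: float = 3.0,
    noise_sd: float = 1.0,
    n_population: int = 178,
    bulk_size: int = 18,
    depth: ReadDepthModel = ReadDepthModel(),
    plexity_mix: dict | None = None,
    duplex_phase: str = "coherent",
    seed: int = 0,
    bulk1: str = "high",
) -> BsaDataset:
    """End-to-end simulation of one bulked-segregant experiment.

    Plants parental variants, picks the variant nearest the middle of the
    first chromosome with the requested donor and plexity as the causal
    locus, breeds ``n_population`` F1s, phenotypes them, bulks the two
    ``bulk_size`` tails, and samples reads for the four sequenced samples.
    ``bulk1`` chooses which tail is Bulk1 (ΔSNP-index = Bulk1 − Bulk2).
    Defaults echo the study design: n=178, ~10% tails, depth 60.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    parents = simulate_parents(
        genome, plexity_mix, seed=rng.integers(2**31), duplex_phase=duplex_phase
    )
    frame = parents.variant_frame()
    chrom0 = genome.chromosomes[0][0]
    mid = genome.chromosomes[0][1] // 2
    eligible = frame[
        (frame["chrom"] == chrom0)
        & (frame["donor"] == qtl_donor)
        & (frame["plexity"] == qtl_plexity)
    ]
    if eligible.empty:
        raise EmptyDatasetError("no eligible causal variant; adjust the plexity mix")
    causal = int((eligible["pos"] - mid).abs().idxmin())

    population = simulate_population(parents, n_population, seed=rng.integers(2**31))
    qtl = QtlModel(causal, qtl_mode, effect, noise_sd)
    phenotypes = assign_phenotypes(population, qtl, seed=rng.integers(2**31))
    low, high, fractions = select_bulks(phenotypes, BulkSpec(bulk_size, bulk_size))
    bulk1_set, bulk2_set = (high, low) if bulk1 == "high" else (low, high)

    read_rng = np.random.default_rng(rng.integers(2**31))
    obs = frame[["chrom", "pos", "ref", "alt"]].copy()
    for name, fractions_vec in (
        ("p1", parent_allele_fractions(parents, "P1")),
        ("p2", parent_allele_fractions(parents, "P2")),
        ("bulk1", bulk_allele_fractions(population, bulk1_set)),
        ("bulk2", bulk_allele_fractions(population, bulk2_set)),
    ):
        ref, alt = sample_reads(fractions_vec, depth, read_rng)
        obs[f"{name}_ref"] = ref
        obs[f"{name}_alt"] = alt

    return BsaDataset(
        parents, population, phenotypes, low, high, fractions, obs, qtl
    )
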