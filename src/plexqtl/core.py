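"""Plexity-aware QTL-seq statistics for polyploid F1 bulked-segregant data.

The pipeline operates on a table of variant observations (per-sample
REF/ALT read depths for two parents and two phenotype-tail bulks):

1. donor-variant filtering — keep variants whose donor-parent SNP-index
   falls in the plexity-specific range (simplex 0.10–0.36, duplex
   0.37–0.63), whose other parent is devoid of the allele, and whose
   samples are all covered to at least ``min_depth``;
2. ΔSNP-index and P values against a Monte-Carlo F1 null (random
   tetrasomic segregation, no QTL, binomial read sampling), with
   depth-conditional 95%/99% confidence bands;
3. 100-kb / 20-kb-step sliding-window aggregation;
4. candidate-region calling: windows where the count of P99 QTL-deduced
   variants exceeds a threshold in exactly one ΔSNP-index direction,
   merged into regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genetics import CrossSpec, progeny_dosage_distribution

SAMPLES = ("P1", "P2", "Bulk1", "Bulk2")

#: SNP-index windows that capture ~95% of donor-parent read draws at depth
#: >= 40 for each plexity (binomial concentration around m/ploidy).
DEFAULT_P2_INDEX_RANGE = {1: (0.10, 0.36), 2: (0.37, 0.63)}


@dataclass(frozen=True)
class PlexityFilterConfig:
    """Donor-variant selection parameters.

    ``nplex`` chooses the target plexity (1 simplex, 2 duplex); the donor
    parent's SNP-index must fall inside ``p2_index_range`` (closed), the
    other parent must be effectively nulliplex (index <= ``p1_max_index``
    and at most ``p1_max_alt_reads`` ALT reads), and all four samples must
    reach ``min_depth`` total reads.
    """

    nplex: int = 1
    p2_index_range: tuple[float, float] | None = None
    min_depth: int = 40
    p1_max_index: float = 0.02
    p1_max_alt_reads: int = 1

    def __post_init__(self) -> None:
        if self.nplex not in (1, 2):
            raise ValueError("nplex must be 1 (simplex) or 2 (duplex)")
        if self.p2_index_range is None:
            object.__setattr__(
                self, "p2_index_range", DEFAULT_P2_INDEX_RANGE[self.nplex]
            )
        lo, hi = self.p2_index_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("p2_index_range must satisfy 0 <= low < high <= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def _index(alt: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """SNP-index = ALT/(REF+ALT); NaN where a sample has no reads."""
    total = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, alt / np.where(total > 0, total, 1), np.nan)


def filter_donor_variants(
    observations: pd.DataFrame, config: PlexityFilterConfig, donor: str = "P2"
) -> pd.DataFrame:
    """Select donor variants of the target plexity.

    ``observations`` must carry ``{sample}_ref`` / ``{sample}_alt`` depth
    columns for P1, P2, Bulk1, Bulk2.  Returns the kept rows with SNP-index
    columns (``p1_index`` … ``bulk2_index``) and a ``plexity`` tag added.
    """
    if donor not in ("P1", "P2"):
        raise ValueError("donor must be 'P1' or 'P2'")
    needed = [f"{s.lower()}_{a}" for s in SAMPLES for a in ("ref", "alt")]
    missing = [c for c in needed if c not in observations.columns]
    if missing:
        raise ValueError(f"observations missing depth columns: {missing}")

    obs = observations.copy()
    for s in SAMPLES:
        key = s.lower()
        obs[f"{key}_index"] = _index(
            obs[f"{key}_alt"].to_numpy(float), obs[f"{key}_ref"].to_numpy(float)
        )

    other = "P1" if donor == "P2" else "P2"
    dkey, okey = donor.lower(), other.lower()
    lo, hi = config.p2_index_range

    depth_ok = np.ones(len(obs), dtype=bool)
    for s in SAMPLES:
        key = s.lower()
        depth_ok &= (obs[f"{key}_ref"] + obs[f"{key}_alt"]).to_numpy() >= config.min_depth

    donor_idx = obs[f"{dkey}_index"].to_numpy()
    other_idx = obs[f"{okey}_index"].to_numpy()
    other_alt = obs[f"{okey}_alt"].to_numpy()
    keep = (
        depth_ok
        & (donor_idx >= lo)
        & (donor_idx <= hi)
        & (other_idx <= config.p1_max_index)
        & (other_alt <= config.p1_max_alt_reads)
    )
    out = obs.loc[keep].copy()
    out["donor"] = donor
    out["plexity"] = config.nplex
    return out.reset_index(drop=True)


def simulate_index_range_coverage(
    cross: CrossSpec,
    depth: int,
    index_range: tuple[float, float],
    replicates: int = 0,
    seed: int | None = None,
) -> float:
    """Probability that a donor variant's read-based SNP-index falls in a range.

    Reads at a donor variant are Binomial(depth, m/ploidy); the coverage of
    the closed interval is the binomial mass on {k : low <= k/depth <= high}.
    With ``replicates`` = 0 the exact sum of the pmf is returned; otherwise a
    Monte-Carlo estimate over ``replicates`` draws.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    lo, hi = index_range
    if not lo < hi:
        raise ValueError("empty index range")
    p = cross.donor_plexity / cross.ploidy
    if replicates:
        rng = np.random.default_rng(seed)
        k = rng.binomial(depth, p, size=replicates)
        frac = k / depth
        return float(np.mean((frac >= lo) & (frac <= hi)))
    k = np.arange(depth + 1)
    inside = (k / depth >= lo) & (k / depth <= hi)
    return float(binom.pmf(k[inside], depth, p).sum())


def _bin_depth(depth: float, width: int = 10) -> int:
    """Depth bin representative: nearest multiple of ``width`` (min width)."""
    return max(width, int(round(depth / width)) * width)


@dataclass
class NullThresholds:
    """Depth-conditional confidence bands of the no-QTL ΔSNP-index null.

    For each (bulk1 depth, bulk2 depth) bin, R replicates of the F1 null are
    simulated: each bulk's n genotypes are drawn from the tetrasomic progeny
    dosage distribution with no selection, pooled into an allele fraction
    f_b = Σdosage/(ploidy·n_b), reads drawn Binomial(d_b, f_b), and
    Δ = k1/d1 − k2/d2.  Bands are the empirical two-sided 95%/99% quantiles
    (reported as the plotted confidence thresholds); the sorted |Δ| sample
    is kept for the P values that drive significance classing.
    """

    cross: CrossSpec
    n1: int
    n2: int
    replicates: int = 10_000
    seed: int = 0
    bin_width: int = 10
    _bands: dict[tuple[int, int], dict] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("bulk sizes must be >= 1")
        if self.replicates < 1000:
            raise ValueError("need >= 1000 replicates to resolve the 99% band")
        dist = progeny_dosage_distribution(self.cross)
        self._dosages = np.array(sorted(dist), dtype=float)
        self._probs = np.array([dist[int(d)] for d in self._dosages])

    def _simulate_bin(self, d1: int, d2: int) -> dict:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(d1, d2))
        )
        R = self.replicates
        f1 = (
            rng.choice(self._dosages, size=(R, self.n1), p=self._probs).sum(axis=1)
            / (self.cross.ploidy * self.n1)
        )
        f2 = (
            rng.choice(self._dosages, size=(R, self.n2), p=self._probs).sum(axis=1)
            / (self.cross.ploidy * self.n2)
        )
        delta = rng.binomial(d1, f1) / d1 - rng.binomial(d2, f2) / d2
        lo99, lo95, hi95, hi99 = np.quantile(delta, [0.005, 0.025, 0.975, 0.995])
        return {
            "lower99": float(lo99),
            "lower95": float(lo95),
            "upper95": float(hi95),
            "upper99": float(hi99),
            "sorted_abs": np.sort(np.abs(delta)),
        }

    def for_depths(self, d1: float, d2: float) -> dict:
        """Band record for a bulk depth pair (built lazily, cached per bin)."""
        key = (_bin_depth(d1, self.bin_width), _bin_depth(d2, self.bin_width))
        if key not in self._bands:
            self._bands[key] = self._simulate_bin(*key)
        return self._bands[key]


def build_null_thresholds(
    cross: CrossSpec,
    n1: int,
    n2: int,
    depth_pairs: list[tuple[int, int]],
    replicates: int = 10_000,
    seed: int = 0,
) -> NullThresholds:
    """Pre-simulate null bands for a set of bulk depth pairs."""
    thr = NullThresholds(cross, n1, n2, replicates, seed)
    for d1, d2 in depth_pairs:
        thr.for_depths(d1, d2)
    return thr


def compute_variant_stats(
    filtered: pd.DataFrame, thresholds: NullThresholds
) -> pd.DataFrame:
    """ΔSNP-index, two-sided P value, and significance class per variant.

    Δ = index(Bulk1) − index(Bulk2).  The P value is the add-one-smoothed
    two-sided tail fraction of the null, (|Δnull| >= |Δ| count + 1)/(R + 1).
    A variant is classed P99 when P <= 0.01 and P95 when P <= 0.05 (the
    boundary counts as significant).  Classing through the P value rather
    than by raw band-crossing keeps the nominal type-I rates at fixed read
    depth, where Δ sits on a 1/depth lattice and an empirical quantile that
    lands on a lattice point would otherwise sweep in its whole tie mass.
    Direction is the sign of Δ.
    """
    out = filtered.copy()
    d1 = (out["bulk1_ref"] + out["bulk1_alt"]).to_numpy(float)
    d2 = (out["bulk2_ref"] + out["bulk2_alt"]).to_numpy(float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("zero bulk depth in filtered observations")
    idx1 = out["bulk1_alt"].to_numpy(float) / d1
    idx2 = out["bulk2_alt"].to_numpy(float) / d2
    delta = idx1 - idx2

    R = thresholds.replicates
    pvals = np.empty(len(out))
    cls = np.full(len(out), "none", dtype=object)
    for i, (dd1, dd2, dv) in enumerate(zip(d1, d2, delta)):
        band = thresholds.for_depths(dd1, dd2)
        tail = R - np.searchsorted(band["sorted_abs"], abs(dv), side="left")
        pvals[i] = (tail + 1) / (R + 1)
        if pvals[i] <= 0.01:
            cls[i] = "P99"
        elif pvals[i] <= 0.05:
            cls[i] = "P95"

    out["bulk1_index"] = idx1
    out["bulk2_index"] = idx2
    out["delta_index"] = delta
    out["p_value"] = pvals
    out["significance"] = cls
    out["direction"] = np.where(delta > 0, "positive", np.where(delta < 0, "negative", "none"))
    return out


def sliding_window_stats(
    stats: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    window_size: int = 100_000,
    step: int = 20_000,
) -> pd.DataFrame:
    """Sliding-window aggregates of variant statistics.

    Windows of ``window_size`` bp tile each chromosome at ``step``-bp
    increments (half-open [start, end) internally, 0-based; reported 1-based
    inclusive).  A variant contributes to every window containing its
    position.  Per window: variant count, mean bulk indices, mean Δ, mean
    −log10 P, and directional significant-variant counts — the P95 counts
    include everything outside the 95% band (so P99 variants as well), the
    P99 counts only variants outside the 99% band.
    """
    if step > window_size:
        raise ValueError("step must not exceed window size")
    if chrom_lengths is None:
        chrom_lengths = (
            stats.groupby("chrom")["pos"].max().astype(int).to_dict() if len(stats) else {}
        )
    rows = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        sub = stats[stats["chrom"] == chrom] if len(stats) else stats
        pos0 = sub["pos"].to_numpy(int) - 1 if len(sub) else np.array([], int)
        for start in range(0, max(length, 1), step):
            end = min(start + window_size, length)
            mask = (pos0 >= start) & (pos0 < end)
            n = int(mask.sum())
            row = {
                "chrom": chrom,
                "start": start + 1,
                "end": end,
                "n_variants": n,
                "mean_bulk1_index": np.nan,
                "mean_bulk2_index": np.nan,
                "mean_delta_index": np.nan,
                "mean_neglog10_p": np.nan,
                "p95_pos": 0,
                "p95_neg": 0,
                "p99_pos": 0,
                "p99_neg": 0,
            }
            if n:
                w = sub.loc[mask]
                sig = w["significance"].to_numpy()
                pos_dir = w["direction"].to_numpy() == "positive"
                neg_dir = w["direction"].to_numpy() == "negative"
                sig95 = (sig == "P95") | (sig == "P99")
                sig99 = sig == "P99"
                row.update(
                    mean_bulk1_index=float(w["bulk1_index"].mean()),
                    mean_bulk2_index=float(w["bulk2_index"].mean()),
                    mean_delta_index=float(w["delta_index"].mean()),
                    mean_neglog10_p=float(np.mean(-np.log10(w["p_value"]))),
                    p95_pos=int(np.sum(sig95 & pos_dir)),
                    p95_neg=int(np.sum(sig95 & neg_dir)),
                    p99_pos=int(np.sum(sig99 & pos_dir)),
                    p99_neg=int(np.sum(sig99 & neg_dir)),
                )
            rows.append(row)
            if end >= length:
                break
    columns = [
        "chrom", "start", "end", "n_variants", "mean_bulk1_index",
        "mean_bulk2_index", "mean_delta_index", "mean_neglog10_p",
        "p95_pos", "p95_neg", "p99_pos", "p99_neg",
    ]
    return pd.DataFrame(rows, columns=columns)


def call_candidate_regions(
    windows: pd.DataFrame, count_threshold: int = 100
) -> pd.DataFrame:
    """Directional candidate-QTL regions from window P99 counts.

    A window qualifies when its P99 variant count strictly exceeds
    ``count_threshold`` in exactly one ΔSNP-index direction (an asymmetric
    excess; windows hot in both directions reflect depth noise in dense
    regions, not a QTL).  Overlapping or bookended qualifying windows with
    the same direction merge into one region.
    """
    qual = windows[
        ((windows["p99_pos"] > count_threshold) ^ (windows["p99_neg"] > count_threshold))
    ].copy()
    if qual.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "direction", "peak_p99_count"]
        )
    qual["direction"] = np.where(
        qual["p99_pos"] > count_threshold, "positive", "negative"
    )
    qual["count"] = np.where(
        qual["direction"] == "positive", qual["p99_pos"], qual["p99_neg"]
    )
    regions = []
    for (chrom, direction), grp in qual.groupby(["chrom", "direction"], sort=True):
        grp = grp.sort_values("start")
        cur = None
        for _, w in grp.iterrows():
            if cur is not None and w["start"] <= cur["end"] + 1:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["peak_p99_count"] = max(cur["peak_p99_count"], int(w["count"]))
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "direction": direction,
                    "peak_p99_count": int(w["count"]),
                }
        regions.append(cur)
    out = pd.DataFrame(regions).sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


@dataclass
class QtlseqResult:
    """Variant-, window-, and region-level outputs of one analysis orientation."""

    donor: str
    plexity: int
    variants: pd.DataFrame
    windows: pd.DataFrame
    regions: pd.DataFrame


def run_qtlseq(
    observations: pd.DataFrame,
    config: PlexityFilterConfig,
    donor: str = "P2",
    ploidy: int = 4,
    n1: int = 18,
    n2: int = 18,
    chrom_lengths: dict[str, int] | None = None,
    window_size: int = 100_000,
    step: int = 20_000,
    count_threshold: int = 100,
    replicates: int = 10_000,
    seed: int = 0,
) -> QtlseqResult:
    """Full plexity-aware QTL-seq analysis for one donor orientation."""
    cross = CrossSpec(ploidy=ploidy, donor_plexity=config.nplex)
    filtered = filter_donor_variants(observations, config, donor)
    thresholds = NullThresholds(cross, n1, n2, replicates, seed)
    stats = compute_variant_stats(filtered, thresholds)
    windows = sliding_window_stats(stats, chrom_lengths, window_size, step)
    regions = call_candidate_regions(windows, count_threshold)
    regions = regions.assign(donor=donor, plexity=config.nplex)
    return QtlseqResult(donor, config.nplex, stats, windows, regions)


def run_both_orientations(
    observations: pd.DataFrame, config: PlexityFilterConfig, **kwargs
) -> dict[str, QtlseqResult]:
    """Repeat the analysis with the parents swapped, to find QTLs from either donor."""
    return {
        donor: run_qtlseq(observations, config, donor=donor, **kwargs)
        for donor in ("P1", "P2")
    }


def simulate_null_observations(
    cross: CrossSpec,
    n_variants: int,
    n1: int = 18,
    n2: int = 18,
    depth: int = 60,
    parent_depth: int = 60,
    seed: int = 0,
    chrom: str = "chr01",
    spacing: int = 400,
) -> pd.DataFrame:
    """No-QTL observations with independently segregating variants.

    Each variant's bulk genotypes are drawn fresh from the tetrasomic
    progeny distribution (no linkage, no selection) and reads are binomial —
    exactly the null model of :class:`NullThresholds`.  Used by the
    null-calibrate utility to check the type-I error of the P95/P99 classes.
    Parent depths are drawn at the donor's expected index so every variant
    passes the plexity filter.
    """
    rng = np.random.default_rng(seed)
    dist = progeny_dosage_distribution(cross)
    dosages = np.array(sorted(dist), dtype=float)
    probs = np.array([dist[int(d)] for d in dosages])
    f1 = rng.choice(dosages, size=(n_variants, n1), p=probs).sum(1) / (cross.ploidy * n1)
    f2 = rng.choice(dosages, size=(n_variants, n2), p=probs).sum(1) / (cross.ploidy * n2)
    b1_alt = rng.binomial(depth, f1)
    b2_alt = rng.binomial(depth, f2)
    p_donor = cross.donor_plexity / cross.ploidy
    p2_alt = rng.binomial(parent_depth, np.full(n_variants, p_donor))
    pos = (np.arange(n_variants) + 1) * spacing
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "p1_ref": parent_depth,
            "p1_alt": 0,
            "p2_ref": parent_depth - p2_alt,
            "p2_alt": p2_alt,
            "bulk1_ref": depth - b1_alt,
            "bulk1_alt": b1_alt,
            "bulk2_ref": depth - b2_alt,
            "bulk2_alt": b2_alt,
        }
    )
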