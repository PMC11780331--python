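"""Allele-dosage (plexity) genotyping from marker assays.

Calls nulliplex / simplex / duplex dosage per individual from three assay
families — qPCR relative allele dosage (ΔCt), fragment-analysis peak-height
ratios, and amplicon-sequencing ALT read fractions — bins the measurements
into dosage classes, forms a per-individual consensus across assays, and
tests the population's segregation ratio by χ² goodness of fit.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chisquare

NULLIPLEX = "nulliplex"
SIMPLEX = "simplex"
DUPLEX = "duplex"
UNCLASSIFIED = "unclassified"
UNRESOLVED = "unresolved"

#: Ordered dosage classes, low to high.
DOSAGE_CLASSES = (NULLIPLEX, SIMPLEX, DUPLEX)

# Default measurement bins per assay type, (low, high) closed intervals for
# (nulliplex, simplex, duplex).  qPCR dosage is on the simplex-calibrator
# scale (simplex mix = 1.0); fragment is ALT/REF peak-height ratio; amplicon
# is ALT reads / total reads.  Where simplex and duplex share an endpoint
# the boundary value resolves to duplex (the interval is split in the middle).
DEFAULT_BINS: dict[str, dict[str, tuple[float, float]]] = {
    "qpcr": {NULLIPLEX: (0.0, 0.1), SIMPLEX: (0.4, 1.5), DUPLEX: (1.5, 2.2)},
    "fragment": {NULLIPLEX: (0.05, 0.15), SIMPLEX: (0.25, 0.55), DUPLEX: (0.55, 1.15)},
    "amplicon": {NULLIPLEX: (0.0, 0.025), SIMPLEX: (0.150, 0.375), DUPLEX: (0.375, 0.700)},
}


@dataclass
class ClassifierBins:
    """Three ordered measurement intervals mapping a value to a dosage class."""

    bins: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        lows = [self.bins[c][0] for c in DOSAGE_CLASSES]
        highs = [self.bins[c][1] for c in DOSAGE_CLASSES]
        if any(lo > hi for lo, hi in zip(lows, highs)):
            raise ValueError("each bin must satisfy low <= high")
        # ordered and non-overlapping except possibly a shared endpoint
        for i in range(2):
            if highs[i] > lows[i + 1]:
                raise ValueError("bins must be ordered and non-overlapping")

    @classmethod
    def default(cls, assay_type: str) -> "ClassifierBins":
        try:
            return cls(dict(DEFAULT_BINS[assay_type]))
        except KeyError:
            raise ValueError(f"unknown assay type {assay_type!r}") from None


@dataclass
class DosageCall:
    """Consensus dosage call for one individual across assays."""

    individual: str
    assay_calls: dict[str, str] = field(default_factory=dict)
    consensus: str = UNRESOLVED
    concordant: bool = False


def dosage_from_qpcr(
    ct_sample: float,
    ct_calibrator: float,
    ct_reference_sample: float | None = None,
    ct_reference_calibrator: float | None = None,
) -> float:
    """Relative allele dosage from qPCR Ct values (simplex calibrator = 1.0).

    Uses relative quantification against a calibrator sample (an equal
    parental DNA mix that mimics a simplex genotype):

        dosage = 2 ** (Ct_calibrator - Ct_sample)

    When reference-amplicon Cts are supplied (crude-extract use, where
    template amounts vary), the ΔΔCt form normalizes each Ct by the
    sample's reference amplicon first.
    """
    if not math.isfinite(ct_sample) or not math.isfinite(ct_calibrator):
        raise ValueError("Ct values must be finite")
    if (ct_reference_sample is None) != (ct_reference_calibrator is None):
        raise ValueError("reference Cts must be given for both sample and calibrator")
    if ct_reference_sample is not None:
        d_sample = ct_sample - ct_reference_sample
        d_cal = ct_calibrator - ct_reference_calibrator
        return float(2.0 ** (d_cal - d_sample))
    return float(2.0 ** (ct_calibrator - ct_sample))


def classify_dosage(value: float, bins: ClassifierBins | str) -> str:
    """Map one measurement to nulliplex/simplex/duplex, or unclassified.

    Intervals are closed; a value on a boundary shared by two classes is
    assigned the higher dosage class, so classification is monotone in the
    measurement.  Values outside every bin are unclassified.
    """
    if isinstance(bins, str):
        bins = ClassifierBins.default(bins)
    if not math.isfinite(value):
        return UNCLASSIFIED
    for cls in reversed(DOSAGE_CLASSES):  # duplex first: shared endpoints go up
        lo, hi = bins.bins[cls]
        if lo <= value <= hi:
            return cls
    return UNCLASSIFIED


def consensus_call(individual: str, assay_calls: dict[str, str]) -> DosageCall:
    """Majority-rule consensus over the non-missing assay calls of one line.

    Unclassified calls count as missing.  The modal class wins; an exact
    tie, or no classifiable call at all, yields ``unresolved``.  The
    concordance flag is set when every non-missing call agrees.
    """
    if not assay_calls:
        raise ValueError("at least one assay call is required")
    valid = [c for c in assay_calls.values() if c in DOSAGE_CLASSES]
    if not valid:
        return DosageCall(individual, dict(assay_calls), UNRESOLVED, False)
    counts = Counter(valid)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        consensus = UNRESOLVED
    else:
        consensus = top[0][0]
    concordant = len(counts) == 1
    return DosageCall(individual, dict(assay_calls), consensus, concordant)


def segregation_chi_square(
    observed: list[int] | np.ndarray, ratio: list[float] | np.ndarray
) -> tuple[float, int, float, np.ndarray]:
    """χ² goodness-of-fit of observed genotype counts to an expected ratio.

    For a duplex-by-nulliplex tetraploid cross the expected
    nulliplex:simplex:duplex ratio is 1:4:1; with n=178 observed as
    39:101:38 this gives expected counts 29.7:118.7:29.7 and P ≈ 0.020.

    Returns (χ² statistic, degrees of freedom, P value, expected counts).
    """
    obs = np.asarray(observed, dtype=float)
    weights = np.asarray(ratio, dtype=float)
    if obs.shape != weights.shape:
        raise ValueError("observed and ratio must have the same length")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if np.any(weights <= 0):
        raise ValueError("ratio weights must be positive")
    expected = obs.sum() * weights / weights.sum()
    stat, p = chisquare(obs, expected)
    df = len(obs) - 1
    return float(stat), df, float(p), expected


def concordance_summary(calls: list[DosageCall]) -> tuple[int, int, int]:
    """Population concordance: (n concordant, n total, percent to nearest integer)."""
    if not calls:
        raise ValueError("empty population")
    n_conc = sum(1 for c in calls if c.concordant)
    n_total = len(calls)
    percent = int(round(100.0 * n_conc / n_total))
    return n_conc, n_total, percent


def genotype_population(
    measurements: pd.DataFrame,
    bins: dict[str, ClassifierBins] | None = None,
) -> pd.DataFrame:
    """Classify and combine assay measurements for a whole population.

    ``measurements`` has columns ``individual``, ``assay`` (a name whose
    type is its prefix up to an optional ``:target`` suffix, e.g.
    ``amplicon:Chr02_41322042``), and ``value``.  Returns one row per
    individual with per-assay calls, the consensus, and the concordance flag.
    """
    required = {"individual", "assay", "value"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    rows = []
    for ind, grp in measurements.groupby("individual", sort=True):
        assay_calls: dict[str, str] = {}
        for _, rec in grp.iterrows():
            assay = str(rec["assay"])
            atype = assay.split(":", 1)[0]
            b = bins[atype] if bins is not None else ClassifierBins.default(atype)
            assay_calls[assay] = classify_dosage(float(rec["value"]), b)
        call = consensus_call(str(ind), assay_calls)
        rows.append(
            {
                "individual": call.individual,
                **{f"call_{a}": c for a, c in sorted(call.assay_calls.items())},
                "consensus": call.consensus,
                "concordant": call.concordant,
            }
        )
    return pd.DataFrame(rows)
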