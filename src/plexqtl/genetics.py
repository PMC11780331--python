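"""Tetrasomic segregation model for autopolyploid crosses.

An autopolyploid with ploidy 2k transmits a random k-subset of its 2k
homologous chromosomes to each gamete (random chromosomal segregation,
no double reduction).  When one parent carries the alternative allele on
``m`` of its homologs (plexity ``m``: nulliplex 0, simplex 1, duplex 2, ...)
and the other parent is nulliplex, the ALT-copy number transmitted to a
gamete is hypergeometric, which yields the classical F1 ratios: 1:1
(nulliplex:simplex) for a simplex donor and 1:4:1
(nulliplex:simplex:duplex) for a duplex donor in a tetraploid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom


class InvalidModelError(ValueError):
    """Raised for segregation models outside this package's scope (odd ploidy)."""


class UndefinedQtlError(ValueError):
    """Raised when a QTL quantity is requested for a nulliplex donor."""


@dataclass(frozen=True)
class CrossSpec:
    """A donor-by-nulliplex autopolyploid cross.

    Parameters
    ----------
    ploidy
        Homolog copies per locus (4 for cultivated potato).  Must be even:
        odd ploidies do not form balanced gametes under bivalent pairing.
    donor_plexity
        Number of donor-parent homologs carrying the ALT allele
        (``m``; 1 = simplex, 2 = duplex).  The other parent is nulliplex.
    """

    ploidy: int = 4
    donor_plexity: int = 1

    def __post_init__(self) -> None:
        if self.ploidy < 2 or self.ploidy % 2 != 0:
            raise InvalidModelError(
                f"ploidy must be an even integer >= 2, got {self.ploidy}"
            )
        if not 0 <= self.donor_plexity <= self.ploidy:
            raise InvalidModelError(
                f"donor_plexity must be in [0, {self.ploidy}], got {self.donor_plexity}"
            )


def gamete_dosage_distribution(cross: CrossSpec) -> dict[int, float]:
    """ALT-copy distribution in donor gametes.

    A gamete receives ploidy/2 homologs drawn without replacement from the
    donor's ploidy homologs, ``m`` of which carry ALT, so the gamete dosage
    ``j`` is hypergeometric:

        P(j) = C(m, j) * C(ploidy - m, ploidy/2 - j) / C(ploidy, ploidy/2)

    Returns a dict mapping dosage to probability over the non-zero support.
    """
    k = cross.ploidy // 2
    m = cross.donor_plexity
    lo = max(0, m - k)
    hi = min(m, k)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, cross.ploidy, m, k)
    return {int(j): float(p) for j, p in zip(support, probs)}


def progeny_dosage_distribution(cross: CrossSpec) -> dict[int, float]:
    """ALT-copy distribution in F1 progeny of a donor-by-nulliplex cross.

    The nulliplex parent contributes no ALT copies, so progeny dosage
    equals the donor gamete dosage; support lies in [0, ploidy/2].
    """
    return gamete_dosage_distribution(cross)


def expected_bulk_snp_index(cross: CrossSpec) -> float:
    """Expected SNP-index of an unselected F1 bulk: E[dosage]/ploidy = m/(2*ploidy).

    For a tetraploid simplex cross this is 0.125 — the genome-wide
    baseline both bulks hover around away from any QTL.
    """
    dist = progeny_dosage_distribution(cross)
    mean_dosage = sum(j * p for j, p in dist.items())
    return mean_dosage / cross.ploidy


def max_delta_snp_index(cross: CrossSpec) -> float:
    """Largest ΔSNP-index attainable under complete tail selection.

    One bulk composed entirely of the highest-dosage progeny class, the
    other entirely of nulliplex progeny: Δ = max progeny dosage / ploidy
    (0.25 for a tetraploid simplex cross, 0.5 for duplex).
    """
    if cross.donor_plexity == 0:
        raise UndefinedQtlError("a nulliplex donor segregates no QTL allele")
    max_dosage = max(progeny_dosage_distribution(cross))
    return max_dosage / cross.ploidy
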