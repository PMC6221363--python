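"""In-silico RT-PCR and the pairwise intron-precedence decision logic.

The wet-lab design this emulates: for two adjacent introns X (5') and Y
(3'), primer set 1 pairs a forward primer in the exon preceding X with a
reverse primer inside Y, so it only amplifies templates still retaining Y
and resolves whether X is present; primer set 2 pairs a forward primer
inside X with a reverse primer in the exon following Y, resolving Y among
X-retaining templates.  Two bands in both sets mean neither intron waits
for the other; two bands in exactly one set mean the intron interrogated by
that set is removed first; a single full-length band in both sets means no
single-spliced intermediate is detectable at all.

Binding is exact-match (the decision logic is presence/absence of template
classes, not thermodynamics); a "band" merges product lengths closer than a
gel-resolution tolerance, and a template class counts as present only above
a detection-limit frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from intron_order.gene_model import GeneModel, Primer, design_primer
from intron_order.isoform_space import SplicingState, realize_sequence

DEFAULT_MAX_PRODUCT = 3000  # nt; polymerase extension-time surrogate
DEFAULT_DETECTION = 0.005   # minimum template-class frequency seen on a gel
DEFAULT_BAND_TOL = 5        # nt; lengths closer than this co-migrate

VERDICTS = ("no_preference", "X_before_Y", "Y_before_X", "only_unspliced", "inconclusive")


@dataclass(frozen=True)
class PcrProduct:
    state: SplicingState
    length: int
    primer_pair: tuple[Primer, Primer]

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("PCR product length must be positive")


@dataclass(frozen=True)
class PrecedenceCall:
    verdict: str
    bands_set1: tuple[int, ...]
    bands_set2: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def primer_binds(primer: Primer, template: str) -> list[int]:
    """All exact-match start positions of the primer's site on the template.

    Forward primers match the template directly; reverse primers match
    where the template contains the reverse complement of the primer.
    """
    if not template:
        raise ValueError("empty template")
    site = primer.site
    positions = []
    start = template.find(site)
    while start != -1:
        positions.append(start)
        start = template.find(site, start + 1)
    return positions


def _present_states(
    population: Mapping[SplicingState, int], detection: float
) -> list[SplicingState]:
    total = sum(population.values())
    if total == 0:
        return []
    return [st for st, n in population.items() if n / total >= detection]


def predict_products(
    population: Mapping[SplicingState, int],
    model: GeneModel,
    fwd: Primer,
    rev: Primer,
    max_len: int = DEFAULT_MAX_PRODUCT,
    detection: float = DEFAULT_DETECTION,
) -> list[PcrProduct]:
    """One product per detectable template state where both primers bind uniquely.

    Product length runs from the forward primer 5' start to the reverse
    primer 3' end on the realized template.  Templates where either primer
    binds more than once are ambiguous and yield no product.
    """
    products = []
    for st in sorted(_present_states(population, detection)):
        template = realize_sequence(model, st)
        fpos = primer_binds(fwd, template)
        rpos = primer_binds(rev, template)
        if len(fpos) != 1 or len(rpos) != 1:
            continue  # absent, or ambiguous multi-site binding
        length = rpos[0] + len(rev.sequence) - fpos[0]
        if 0 < length <= max_len and fpos[0] < rpos[0]:
            products.append(PcrProduct(st, length, (fwd, rev)))
    return products


def merge_bands(lengths: Sequence[int], tol: int = DEFAULT_BAND_TOL) -> tuple[int, ...]:
    """Collapse product lengths that would co-migrate on a gel."""
    bands: list[int] = []
    for length in sorted(set(lengths)):
        if bands and length - bands[-1] < tol:
            continue
        bands.append(length)
    return tuple(bands)


def precedence_primers(
    model: GeneModel, x: int, y: int, primer_length: int = 20
) -> tuple[tuple[Primer, Primer], tuple[Primer, Primer]]:
    """Build the two primer sets of the pairwise test for adjacent introns x < y."""
    set1 = (
        design_primer(model, f"e{x}F", "forward", "exon", x, -primer_length, primer_length),
        design_primer(model, f"i{y}R", "reverse", "intron", y, 0, primer_length),
    )
    set2 = (
        design_primer(model, f"i{x}F", "forward", "intron", x, -primer_length, primer_length),
        design_primer(model, f"e{y + 1}R", "reverse", "exon", y + 1, 0, primer_length),
    )
    return set1, set2


def call_precedence(
    population: Mapping[SplicingState, int],
    model: GeneModel,
    intron_x: int,
    intron_y: int,
    detection: float = DEFAULT_DETECTION,
    max_len: int = DEFAULT_MAX_PRODUCT,
    band_tol: int = DEFAULT_BAND_TOL,
) -> PrecedenceCall:
    """Pairwise removal-order verdict for adjacent introns X (5') and Y (3').

    The verdict is a pure function of which of the three informative
    template classes — both retained, X spliced/Y retained, Y spliced/X
    retained — are present above the detection limit.
    """
    if intron_y != intron_x + 1:
        raise ValueError(
            f"precedence test requires adjacent introns, got {intron_x},{intron_y}"
        )
    model.intron(intron_x), model.intron(intron_y)

    set1, set2 = precedence_primers(model, intron_x, intron_y)
    prod1 = predict_products(population, model, *set1, max_len=max_len, detection=detection)
    prod2 = predict_products(population, model, *set2, max_len=max_len, detection=detection)
    bands1 = merge_bands([p.length for p in prod1], band_tol)
    bands2 = merge_bands([p.length for p in prod2], band_tol)

    present = _present_states(population, detection)
    both = any(s.retained(intron_x) and s.retained(intron_y) for s in present)
    x_spliced = any(not s.retained(intron_x) and s.retained(intron_y) for s in present)
    y_spliced = any(s.retained(intron_x) and not s.retained(intron_y) for s in present)

    if both and x_spliced and y_spliced:
        verdict = "no_preference"
    elif both and x_spliced:
        verdict = "X_before_Y"
    elif both and y_spliced:
        verdict = "Y_before_X"
    elif both:
        verdict = "only_unspliced"
    else:
        verdict = "inconclusive"
    return PrecedenceCall(verdict, bands1, bands2)


def rbcs_order_test(
    population: Mapping[SplicingState, int],
    model: GeneModel,
    primers: Mapping[str, Primer],
    detection: float = DEFAULT_DETECTION,
    max_len: int = DEFAULT_MAX_PRODUCT,
) -> dict[str, dict]:
    """Outron-vs-first-intron trans-splicing test on an rbcS-style model.

    ``primers`` maps labels "1" and "2" (forward, in the outron), "3"
    (reverse, in intron 1), "4" (reverse, in exon 2) and "SL" (forward, on
    the splice leader).  Reports, for each primer set of the published
    design, whether any template in the population yields a product and at
    which lengths.  A product from the SL-3 set is the signature of a
    transcript that has been trans-spliced while its first nonconventional
    intron is still unspliced.
    """
    if model.outron is None or model.splice_leader is None:
        raise ValueError("rbcS order test needs a model with outron and splice leader")
    sets = [("1", "3"), ("2", "3"), ("SL", "4"), ("1", "4"), ("SL", "3")]
    table: dict[str, dict] = {}
    for f_label, r_label in sets:
        prods = predict_products(
            population, model, primers[f_label], primers[r_label],
            max_len=max_len, detection=detection,
        )
        bands = merge_bands([p.length for p in prods])
        table[f"{f_label}-{r_label}"] = {
            "product_observed": bool(prods),
            "band_lengths": list(bands),
        }
    return table
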