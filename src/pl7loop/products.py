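"""Observed oligosaccharide product distributions and concordance scoring.

A product distribution maps the degree of polymerization (Dp) of each
oligomer to its percentage of total product, typically derived from HPLC
peak areas at the end of the degradation's middle stage.  Distributions
are grouped by their main product: Dp2/Dp3-predominant distributions pair
with the long-loop1 (SMALL_OLIGO) prediction, everything else with the
short-loop1 (LARGE_OLIGO) prediction.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .errors import PairingError, ValidationError
from .pipeline import DpClass, DpPrediction


class GroupLabel(enum.Enum):
    TRI_DI_PREDOMINANT = "TRI_DI_PREDOMINANT"
    LARGER_OLIGO_PREDOMINANT = "LARGER_OLIGO_PREDOMINANT"


#: Which observed group each predicted class corresponds to.
CLASS_TO_GROUP = {
    DpClass.SMALL_OLIGO: GroupLabel.TRI_DI_PREDOMINANT,
    DpClass.LARGE_OLIGO: GroupLabel.LARGER_OLIGO_PREDOMINANT,
}


@dataclasses.dataclass(frozen=True)
class ProductDistribution:
    """Observed Dp -> percent table for one enzyme."""

    id: str
    percents: Mapping[int, float]
    provenance: str = "hplc-peak-areas"

    def __post_init__(self) -> None:
        if not self.percents:
            raise ValidationError(f"{self.id}: empty product distribution")
        for dp, pct in self.percents.items():
            if dp < 2:
                raise ValidationError(f"{self.id}: Dp must be >= 2, got {dp}")
            if pct < 0:
                raise ValidationError(f"{self.id}: negative percent at Dp{dp}")
        total = sum(self.percents.values())
        if abs(total - 100.0) > 0.5:
            raise ValidationError(
                f"{self.id}: percents sum to {total:.2f}, expected 100 +/- 0.5"
            )


@dataclasses.dataclass(frozen=True)
class MainProductCall:
    dp: int
    tied: bool


@dataclasses.dataclass(frozen=True)
class ConcordanceReport:
    """2x2 cross-tabulation of predicted class vs observed group."""

    counts: Mapping[tuple[str, str], int]  # (DpClass value, GroupLabel value) -> n
    agreement: float
    n: int


def normalize_distribution(
    id: str, raw_areas: Mapping[int, float], provenance: str = "hplc-peak-areas"
) -> ProductDistribution:
    """Convert raw (e.g. HPLC peak-area) quantities to percents of total."""
    total = sum(raw_areas.values())
    if total <= 0:
        raise ValidationError(f"{id}: all-zero product quantities")
    return ProductDistribution(
        id=id,
        percents={dp: 100.0 * a / total for dp, a in raw_areas.items()},
        provenance=provenance,
    )


def main_product(dist: ProductDistribution) -> MainProductCall:
    """The Dp with maximum percent; ties break toward smaller Dp, flagged."""
    best = max(dist.percents.values())
    winners = sorted(dp for dp, pct in dist.percents.items() if pct == best)
    return MainProductCall(dp=winners[0], tied=len(winners) > 1)


def group_of(dist: ProductDistribution) -> GroupLabel:
    """Observed group: Dp2/Dp3 main product -> TRI_DI, else LARGER_OLIGO."""
    call = main_product(dist)
    if call.dp in (2, 3):
        return GroupLabel.TRI_DI_PREDOMINANT
    return GroupLabel.LARGER_OLIGO_PREDOMINANT


def concordance(
    predictions: Sequence[DpPrediction],
    observations: Sequence[ProductDistribution],
) -> ConcordanceReport:
    """Cross-tabulate predicted classes against observed product groups.

    Pairs by id (both lists must cover the same ids; predictions without a
    class, i.e. screened-out records, are not allowed here).  Agreement is
    the concordant fraction under the class<->group mapping.
    """
    pred_by_id = {p.id: p for p in predictions}
    obs_by_id = {o.id: o for o in observations}
    offenders = sorted(set(pred_by_id) ^ set(obs_by_id))
    if offenders:
        raise PairingError(
            f"unmatched ids between predictions and observations: {offenders}",
            offenders=offenders,
        )
    unclassified = sorted(pid for pid, p in pred_by_id.items() if p.dp_class is None)
    if unclassified:
        raise PairingError(
            f"predictions without a class cannot be scored: {unclassified}",
            offenders=unclassified,
        )
    counts: dict[tuple[str, str], int] = {}
    hits = 0
    for pid in sorted(pred_by_id):
        pred = pred_by_id[pid]
        group = group_of(obs_by_id[pid])
        key = (pred.dp_class.value, group.value)
        counts[key] = counts.get(key, 0) + 1
        if CLASS_TO_GROUP[pred.dp_class] is group:
            hits += 1
    n = len(pred_by_id)
    return ConcordanceReport(counts=counts, agreement=hits / n if n else 0.0, n=n)


def read_distributions(path: Union[str, Path]) -> list[ProductDistribution]:
    """Read ``id<TAB>dp<TAB>percent_or_area`` rows and normalize per id."""
    raw: dict[str, dict[int, float]] = {}
    order: list[str] = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        rid, dp, value = ln.split("\t")
        if rid not in raw:
            raw[rid] = {}
            order.append(rid)
        raw[rid][int(dp)] = float(value)
    return [normalize_distribution(rid, raw[rid]) for rid in order]


def write_concordance(report: ConcordanceReport, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("predicted_class\tobserved_group\tcount\n")
        for (cls, grp), n in sorted(report.counts.items()):
            fh.write(f"{cls}\t{grp}\t{n}\n")
        fh.write(f"# agreement\t{report.agreement:.4f}\tn={report.n}\n")
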