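"""Percent-change and fold-change arithmetic over strain physiology records.

Ships a packaged fixture with the measured physiology of six recombinant
S. cerevisiae strains (CTY and INVSc1 hosts, each carrying the wild-type or
one of two promoter-optimized fungal xylose pathways): growth rate, xylose
uptake rate, and xylitol/glycerol/acetate/ethanol yields with their stated
uncertainties.  Percent changes are rounded half away from zero to whole
percents, matching how such changes are conventionally reported; the exact
value is returned alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

from .errors import TableValueError
from .io import PhysiologyTable, read_physiology_table

_FIXTURE = "physiology_cty_inv.tsv"


def load_strain_physiology() -> PhysiologyTable:
    """Load the packaged six-strain physiology fixture."""
    ref = resources.files("xyloseq.data").joinpath(_FIXTURE)
    with resources.as_file(ref) as path:
        return read_physiology_table(path)


@dataclass(frozen=True)
class PercentChange:
    """Signed percent change from a reference value to a new value."""

    exact: float  # 100 * (new - reference) / reference
    rounded: int  # half away from zero


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def percent_change(reference: float, new: float) -> PercentChange:
    """Percent change of ``new`` relative to ``reference`` (> 0).

    Negative means a decrease: percent_change(0.60, 0.43).rounded == -28.
    """
    if reference <= 0:
        raise TableValueError("reference must be positive")
    if new < 0:
        raise TableValueError("new value must be nonnegative")
    exact = 100.0 * (new - reference) / reference
    return PercentChange(exact=exact, rounded=_round_half_away(exact))


def fold_change(new: float, reference: float) -> float:
    """Ratio new / reference, reference > 0."""
    if reference <= 0:
        raise TableValueError("reference must be positive")
    if new < 0:
        raise TableValueError("new value must be nonnegative")
    return new / reference


def metric_percent_change(
    table: PhysiologyTable, metric: str, from_strain: str, to_strain: str
) -> PercentChange:
    """Percent change of one physiology metric between two strains."""
    return percent_change(table.value(from_strain, metric), table.value(to_strain, metric))


def metric_fold_change(
    table: PhysiologyTable, metric: str, from_strain: str, to_strain: str
) -> float:
    """Fold change of one physiology metric between two strains."""
    return fold_change(table.value(to_strain, metric), table.value(from_strain, metric))
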