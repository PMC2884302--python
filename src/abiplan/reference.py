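"""Published benchmark values used as inputs by regression tests and scripts.

These are the printed summary numbers from a published clinical evaluation of
non-iterative aperture-weight optimization: initial/final cost-function
values of eight patient data sets (head-and-neck, brain and abdomen), and
total monitor units / segment counts of the aperture-based (ABIP) plans
against their beamlet-based (BBIP) comparators for two of those cases.  They
serve as inputs to the package's comparison arithmetic, never as quantities
the package computes.
"""

from typing import NamedTuple


class CostTrial(NamedTuple):
    initial: float
    final: float
    reported_percent: int  # printed nearest-integer reduction


#: Initial/final cost of a single optimization trial per data set.
COST_TRIALS: dict[str, CostTrial] = {
    "A": CostTrial(1225.0, 270.0, 78),
    "B": CostTrial(1345.0, 150.0, 89),
    "C": CostTrial(600.0, 125.0, 79),
    "D": CostTrial(450.0, 79.0, 82),
    "E": CostTrial(1678.0, 330.0, 80),
    "F": CostTrial(360.0, 42.0, 88),
    "G": CostTrial(2580.0, 346.0, 87),
    "H": CostTrial(140.0, 29.0, 79),
}


class DeliveryComparison(NamedTuple):
    bbip: float  # beamlet-based reference plan
    abip: float  # aperture-based plan
    reported_percent: int  # printed reduction (None-checked by tests where consistent)


#: Total MU and segment counts, (BBIP reference, ABIP), with the printed
#: percent reductions.  The Case-B segment cell was printed truncated (57)
#: rather than rounded (58) in the source and is excluded from exact checks.
DELIVERY: dict[str, dict[str, DeliveryComparison]] = {
    "case_a": {
        "mu": DeliveryComparison(768.0, 360.0, 53),
        "segments": DeliveryComparison(84.0, 30.0, 64),
    },
    "case_b": {
        "mu": DeliveryComparison(652.0, 342.0, 48),
        "segments": DeliveryComparison(66.0, 28.0, 57),
    },
}
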