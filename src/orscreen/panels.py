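"""Published in vivo validation outcomes for SlitOR25 and SlitOR31.

Each panel records the single-sensillum-recording outcome of the
molecules selected by the screening workflow for one *Spodoptera
littoralis* receptor: the predicted binders actually tested, plus the
suspected decoys and potential non-binders included as quality
controls. Only the experimentally active compounds are identified by
name (benzyl formate and 3-(3,4-dihydroxyphenyl)propanoic acid for
SlitOR25; 2-methoxy-4-propylphenol for SlitOR31); the remaining tested
molecules enter as anonymous counted outcomes, which is all the
workflow-evaluation arithmetic needs.

These tables are the standard worked example for
:func:`orscreen.triage.evaluate_predictions`.
"""

from __future__ import annotations

from .calibration import ACTIVE, INACTIVE
from .triage import BINDER, NONBINDER_OR_DECOY


def _panel(
    receptor: str,
    n_binders: int,
    active_binders: list[str],
    n_decoys: int,
    n_nonbinders: int,
) -> tuple[dict[str, str], dict[str, str]]:
    predicted: dict[str, str] = {}
    observed: dict[str, str] = {}
    for name in active_binders:
        predicted[name] = BINDER
        observed[name] = ACTIVE
    for i in range(n_binders - len(active_binders)):
        mol = f"{receptor}_binder_{i + 1:02d}"
        predicted[mol] = BINDER
        observed[mol] = INACTIVE
    for i in range(n_decoys):
        mol = f"{receptor}_decoy_{i + 1:02d}"
        predicted[mol] = NONBINDER_OR_DECOY
        observed[mol] = INACTIVE
    for i in range(n_nonbinders):
        mol = f"{receptor}_nonbinder_{i + 1:02d}"
        predicted[mol] = NONBINDER_OR_DECOY
        observed[mol] = INACTIVE
    return predicted, observed


#: SlitOR25 (broadly tuned): 19 predicted binders tested, 2 active;
#: 3 suspected decoys and 5 potential non-binders, none active.
SLITOR25_PANEL = _panel(
    "SlitOR25",
    n_binders=19,
    active_binders=["benzyl formate", "3-(3,4-dihydroxyphenyl)propanoic acid"],
    n_decoys=3,
    n_nonbinders=5,
)

#: SlitOR31 (narrowly tuned, eugenol receptor): 17 predicted binders
#: tested, 1 active; 3 suspected decoys and 5 potential non-binders,
#: none active.
SLITOR31_PANEL = _panel(
    "SlitOR31",
    n_binders=17,
    active_binders=["2-methoxy-4-propylphenol"],
    n_decoys=3,
    n_nonbinders=5,
)

PANELS = {"SlitOR25": SLITOR25_PANEL, "SlitOR31": SLITOR31_PANEL}
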