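"""Clinical screening protocol driven by the model-estimated AHI.

The corrected AHI partitions children into four actions:

* AHI < 1 e/h   -> rule out OSA (with the caveat that persistent symptoms
  still warrant referral to polysomnography);
* 1 <= AHI < 5  -> refer to full PSG (diagnosis uncertain);
* 5 <= AHI < 10 -> recommend treatment;
* AHI >= 10     -> recommend treatment plus additional follow-up, since
  severe OSA may persist after treatment.

Only the middle band consumes a full PSG, so the protocol's resource saving
is the percentage of children whose action is anything but ``refer_psg``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["ACTIONS", "ScreeningDecision", "recommend", "psg_reduction", "screen_cohort"]

ACTIONS = ("rule_out", "refer_psg", "treat", "treat_and_follow_up")

_RULE_OUT_NOTE = "if symptoms persist, referral to PSG is recommended"


@dataclass(frozen=True)
class ScreeningDecision:
    subject_id: str
    ahi_pred: float
    action: str
    note: str = ""


def recommend(ahi_pred: float) -> str:
    """Map a predicted AHI to a screening action (boundaries left-closed)."""
    if ahi_pred < 0:
        raise ValueError("predicted AHI must be >= 0")
    if ahi_pred < 1:
        return "rule_out"
    if ahi_pred < 5:
        return "refer_psg"
    if ahi_pred < 10:
        return "treat"
    return "treat_and_follow_up"


def screen_cohort(
    subject_ids: Sequence[str], ahi_preds: Sequence[float]
) -> list[ScreeningDecision]:
    if len(subject_ids) != len(ahi_preds):
        raise ValueError("need one predicted AHI per subject")
    out = []
    for sid, ahi in zip(subject_ids, ahi_preds):
        action = recommend(ahi)
        note = _RULE_OUT_NOTE if action == "rule_out" else ""
        out.append(ScreeningDecision(sid, float(ahi), action, note))
    return out


def psg_reduction(decisions: Sequence[ScreeningDecision]) -> float:
    """Percent of the cohort whose action avoids a full PSG."""
    if len(decisions) == 0:
        raise ValueError("decision list is empty")
    avoided = sum(1 for d in decisions if d.action != "refer_psg")
    return 100.0 * avoided / len(decisions)
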