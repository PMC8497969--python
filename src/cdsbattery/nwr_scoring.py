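"""Nonword-repetition scoring with a real-word articulatory control.

Each nonword target phoneme is paired by design with the equivalent
phoneme in a matched real word.  Adjudication per target:

* nonword phoneme produced correctly → **correct**;
* nonword wrong but the real-word counterpart also wrong →
  **articulatory_control** (the error is attributed to articulatory
  limitations, not phonological processing, and is not marked incorrect);
* nonword wrong, real word right → **incorrect**.

Items the child fails to repeat after two experimenter prompts are marked
entirely incorrect (the articulatory control does not apply to refusals).

Session accuracy defaults to (correct + articulatory_control) / n_targets,
keeping the full target denominator; an alternative mode drops
articulatory-control targets from the denominator.

Phoneme comparison is an exact segmental match (stress stripped); scoring
is binary with no feature-distance partial credit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .arpabet import strip_stress


class Adjudication(str, Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    ARTICULATORY_CONTROL = "articulatory_control"


class DenominatorMode(str, Enum):
    KEEP = "keep"        # articulatory_control counts as not-incorrect
    EXCLUDE = "exclude"  # articulatory_control removed from the denominator


@dataclass
class NWRStimulus:
    item_id: str
    condition: str                   # "nonword" | "realword"
    syllable_count: int
    target_phonemes: tuple[str, ...]
    paired_item_id: str

    def __post_init__(self) -> None:
        if self.condition not in ("nonword", "realword"):
            raise ValueError(f"bad condition {self.condition!r}")
        if self.syllable_count not in (1, 2, 3):
            raise ValueError("syllable_count must be 1, 2 or 3")
        if not self.target_phonemes:
            raise ValueError("stimulus needs >= 1 target phoneme")


@dataclass
class NWRResponse:
    child_id: str
    item_id: str
    condition: str
    produced: tuple[str | None, ...]   # one slot per target position
    prompts_given: int = 1
    refused: bool = False

    def __post_init__(self) -> None:
        if self.prompts_given > 2:
            raise ValueError("prompts_given may not exceed 2")
        if self.refused and any(p is not None for p in self.produced):
            raise ValueError("a refused item cannot carry produced phonemes")


@dataclass
class NWROutcome:
    child_id: str
    n_targets: int
    n_correct: int
    accuracy: float
    adjudications: list[Adjudication] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError(f"accuracy {self.accuracy} outside [0, 1]")


def score_target(
    nw_produced: str | None,
    nw_target: str,
    rw_produced: str | None,
    rw_target: str | None,
    missing_realword_policy: str = "face_value",
) -> Adjudication:
    """Adjudicate one nonword target against its real-word control.

    A missing real-word response (rw_target None) is handled by policy:
    ``face_value`` scores the nonword on its own (with a warning upstream),
    ``control`` treats an incorrect nonword as articulatory_control.
    """
    nw_ok = _match(nw_produced, nw_target)
    if nw_ok:
        return Adjudication.CORRECT
    if rw_target is None:
        if missing_realword_policy == "control":
            return Adjudication.ARTICULATORY_CONTROL
        return Adjudication.INCORRECT
    rw_ok = _match(rw_produced, rw_target)
    if not rw_ok:
        return Adjudication.ARTICULATORY_CONTROL
    return Adjudication.INCORRECT


def _match(produced: str | None, target: str) -> bool:
    if produced is None:
        return False
    return strip_stress(produced) == strip_stress(target)


def score_item(
    nw_stimulus: NWRStimulus,
    nw_response: NWRResponse,
    rw_stimulus: NWRStimulus | None,
    rw_response: NWRResponse | None,
    missing_realword_policy: str = "face_value",
) -> list[Adjudication]:
    """Per-target adjudications for one nonword item.

    A refusal after the two allowed prompts marks every target incorrect.
    """
    targets = nw_stimulus.target_phonemes
    if nw_response.refused:
        return [Adjudication.INCORRECT] * len(targets)
    produced = _pad(nw_response.produced, len(targets))
    rw_targets: tuple[str | None, ...]
    if rw_stimulus is None or rw_response is None or rw_response.refused:
        rw_targets = (None,) * len(targets)
        rw_produced: tuple[str | None, ...] = (None,) * len(targets)
        if rw_stimulus is None or rw_response is None:
            import logging
            logging.getLogger("cdsbattery").warning(
                "nwr: no real-word control for item %s; scoring at %s",
                nw_stimulus.item_id, missing_realword_policy)
    else:
        if len(rw_stimulus.target_phonemes) != len(targets):
            raise ValueError(
                f"item {nw_stimulus.item_id}: paired real word has "
                f"{len(rw_stimulus.target_phonemes)} targets, expected "
                f"{len(targets)}")
        rw_targets = rw_stimulus.target_phonemes
        rw_produced = _pad(rw_response.produced, len(targets))
    return [
        score_target(produced[i], targets[i], rw_produced[i], rw_targets[i],
                     missing_realword_policy)
        for i in range(len(targets))
    ]


def _pad(produced: tuple[str | None, ...], n: int) -> tuple[str | None, ...]:
    if len(produced) > n:
        raise ValueError("more produced phonemes than target positions")
    return produced + (None,) * (n - len(produced))


def session_accuracy(
    responses: list[NWRResponse],
    stimuli: list[NWRStimulus],
    mode: DenominatorMode | str = DenominatorMode.KEEP,
    missing_realword_policy: str = "face_value",
) -> NWROutcome:
    """Score a full session (one child) over the stimulus inventory."""
    mode = DenominatorMode(mode)
    by_item = {(s.item_id): s for s in stimuli}
    resp_index: dict[tuple[str, str], NWRResponse] = {}
    child_ids = set()
    for r in responses:
        key = (r.item_id, r.condition)
        if key in resp_index:
            raise ValueError(f"duplicate response for item {key}")
        resp_index[key] = r
        child_ids.add(r.child_id)
    child_id = child_ids.pop() if len(child_ids) == 1 else "mixed"

    adjudications: list[Adjudication] = []
    for stim in stimuli:
        if stim.condition != "nonword":
            continue
        nw_resp = resp_index.get((stim.item_id, "nonword"))
        if nw_resp is None:
            raise ValueError(f"no nonword response for item {stim.item_id}")
        rw_stim = by_item.get(stim.paired_item_id)
        rw_resp = resp_index.get((stim.paired_item_id, "realword"))
        adjudications.extend(
            score_item(stim, nw_resp, rw_stim, rw_resp,
                       missing_realword_policy)
        )

    n_correct = sum(a is Adjudication.CORRECT for a in adjudications)
    n_control = sum(
        a is Adjudication.ARTICULATORY_CONTROL for a in adjudications)
    if mode is DenominatorMode.KEEP:
        denom = len(adjudications)
        numer = n_correct + n_control
    else:
        denom = len(adjudications) - n_control
        numer = n_correct
    accuracy = numer / denom if denom else 0.0
    return NWROutcome(
        child_id=child_id,
        n_targets=len(adjudications),
        n_correct=n_correct,
        accuracy=accuracy,
        adjudications=adjudications,
    )


# ---------------------------------------------------------------------------
# stimulus / response tables
# ---------------------------------------------------------------------------

def read_stimuli(path: str | Path) -> list[NWRStimulus]:
    """Stimulus TSV: item_id, condition, syllables, targets (space-sep),
    paired_item_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        NWRStimulus(
            item_id=r.item_id,
            condition=r.condition,
            syllable_count=int(r.syllables),
            target_phonemes=tuple(r.targets.split()),
            paired_item_id=r.paired_item_id,
        )
        for r in df.itertuples()
    ]


def read_responses(path: str | Path) -> list[NWRResponse]:
    """Response TSV: child_id, item_id, condition, produced (space-sep,
    '-' for a null slot), prompts_given, refused (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples():
        produced = tuple(
            None if p == "-" else p for p in r.produced.split()
        ) if r.produced.strip() else ()
        out.append(
            NWRResponse(
                child_id=r.child_id,
                item_id=r.item_id,
                condition=r.condition,
                produced=produced,
                prompts_given=int(r.prompts_given),
                refused=r.refused.strip() in ("1", "true", "True"),
            )
        )
    return out


def write_outcomes(outcomes: list[NWROutcome], path: str | Path) -> None:
    pd.DataFrame(
        {
            "child_id": [o.child_id for o in outcomes],
            "n_targets": [o.n_targets for o in outcomes],
            "n_correct": [o.n_correct for o in outcomes],
            "accuracy": [o.accuracy for o in outcomes],
        }
    ).to_csv(path, index=False)


def synthetic_stimulus_set() -> list[NWRStimulus]:
    """A synthetic 11-item stimulus inventory (not the original task items).

    Mirrors the task design only: 11 nonword/real-word pairs with a
    4 / 4 / 3 split over 1 / 2 / 3 syllables and 33 scoreable phoneme
    targets in the nonword condition, each nonword matched to a real word
    on its target consonants.  The strings themselves are invented.
    """
    # (syllables, targets) per pair; target counts sum to 33
    design = [
        (1, ("B", "AE1")), (1, ("D", "IY1")), (1, ("K", "UW1")),
        (1, ("M", "OW1")),
        (2, ("P", "AH1", "T")), (2, ("S", "EH1", "N")), (2, ("G", "AA1", "F")),
        (2, ("L", "IH1", "D")),
        (3, ("T", "AE1", "N", "SH")), (3, ("F", "OW1", "M", "K")),
        (3, ("R", "UW1", "B", "D", "G")),
    ]
    stimuli: list[NWRStimulus] = []
    for i, (syl, targets) in enumerate(design, start=1):
        nw_id, rw_id = f"nw{i:02d}", f"rw{i:02d}"
        stimuli.append(NWRStimulus(nw_id, "nonword", syl, tuple(targets), rw_id))
        stimuli.append(NWRStimulus(rw_id, "realword", syl, tuple(targets), nw_id))
    n_targets = sum(len(s.target_phonemes) for s in stimuli
                    if s.condition == "nonword")
    assert n_targets == 33, n_targets
    return stimuli
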