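"""Productive-aptitude classification from zoometric indices.

Zoometric practice reads each index as a signal toward dairy or beef
conformation, then weighs the signals into an overall verdict:

* dairy block — TI, BI, AI, DTI, DCI (elliptical deep thorax, short
  body, large girth per stature, fine cannon bone);
* beef block — LBI, PI, TPI, LPI (compact rectangular frame, wide long
  rump relative to stature);
* CEI is purely descriptive (dolichocephalic vs brachycephalic) and
  never votes.

Quantified thresholds exist for only some indices (DTI dairy < 10 /
beef > 11; TPI and LPI beef > 33; AI dairy band 2.5-3.0).  The rest
(TI, BI, LBI, DCI) are classified against configurable heuristic
cutoffs, flagged ``heuristic`` in reports, since the literature argues
them only comparatively ("the lower the TI the more elliptical", a
brevilineal BI, a compact LBI, a high dairy DCI).

The verdict is a majority vote over the nine aptitude-bearing indices:
an index votes with the side its label indicates; an index whose label
is inconclusive (DUAL, or descriptive like PI) votes with its block.
Unanimity gives DAIRY or BEEF outright; a split gives DUAL with a
tendency toward the majority side; a tie (impossible with nine voters
under the default blocks, possible under user reconfiguration) gives
plain DUAL.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .indices import INDEX_CODES, IndexVector

#: Indices whose values argue a dairy conformation.
DAIRY_BLOCK = ("TI", "BI", "AI", "DTI", "DCI")
#: Indices whose values argue a beef conformation.
BEEF_BLOCK = ("LBI", "PI", "TPI", "LPI")


class Label(enum.Enum):
    DAIRY = "DAIRY"
    BEEF = "BEEF"
    DUAL = "DUAL"
    DESCRIPTIVE = "DESCRIPTIVE"


class Verdict(enum.Enum):
    DAIRY = "DAIRY"
    BEEF = "BEEF"
    DUAL_DAIRY_TENDENCY = "DUAL_DAIRY_TENDENCY"
    DUAL_BEEF_TENDENCY = "DUAL_BEEF_TENDENCY"
    DUAL = "DUAL"


@dataclass(frozen=True)
class AptitudeThresholds:
    """Cutoffs used to label each index.

    Quantified defaults: DTI dairy < 10, beef > 11; TPI/LPI beef > 33;
    AI dairy within [2.5, 3.0]; CEI dolichocephalic < 50; PI
    brachypelvic < 100.  Heuristic (comparative-only) defaults: TI
    elliptical-thorax < 60, BI brevilineal < 85, LBI compact < 90, DCI
    dairy > 45.
    """

    dti_dairy_max: float = 10.0
    dti_beef_min: float = 11.0
    tpi_beef_min: float = 33.0
    lpi_beef_min: float = 33.0
    ai_dairy_low: float = 2.5
    ai_dairy_high: float = 3.0
    cei_dolicho_max: float = 50.0
    pi_brachy_max: float = 100.0
    ti_elliptic_max: float = 60.0
    bi_brevilineal_max: float = 85.0
    lbi_compact_max: float = 90.0
    dci_dairy_min: float = 45.0

    #: thresholds with no quantified backing in the zoometric literature
    HEURISTIC = ("ti_elliptic_max", "bi_brevilineal_max",
                 "lbi_compact_max", "dci_dairy_min")

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if isinstance(value, (int, float)) and value <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.dti_dairy_max >= self.dti_beef_min:
            raise ValueError("DTI dairy cutoff must lie below the beef cutoff")
        if self.ai_dairy_low >= self.ai_dairy_high:
            raise ValueError("AI dairy band must have low < high")

    @classmethod
    def from_yaml(cls, path) -> "AptitudeThresholds":
        with open(path, "r", encoding="utf-8") as fh:
            overrides = yaml.safe_load(fh) or {}
        unknown = set(overrides) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown threshold names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in overrides.items()})


@dataclass(frozen=True)
class IndexCall:
    """Classification of one index value."""

    code: str
    value: float
    label: Label
    morphology: str | None = None  # e.g. dolichocephalic, brachypelvic
    heuristic: bool = False        # cutoff lacks a quantified basis
    note: str | None = None


@dataclass(frozen=True)
class AptitudeProfile:
    """Per-index calls plus the overall verdict."""

    calls: Mapping[str, IndexCall]
    verdict: Verdict
    dairy_votes: int = field(default=0)
    beef_votes: int = field(default=0)


def _classify_one(code: str, value: float, t: AptitudeThresholds) -> IndexCall:
    if code == "CEI":
        morphology = (
            "dolichocephalic" if value < t.cei_dolicho_max else "brachycephalic"
        )
        return IndexCall(code, value, Label.DESCRIPTIVE, morphology)
    if code == "TI":
        label = Label.DAIRY if value < t.ti_elliptic_max else Label.BEEF
        shape = "elliptical thorax" if label is Label.DAIRY else "round thorax"
        return IndexCall(code, value, label, shape, heuristic=True)
    if code == "BI":
        label = Label.DAIRY if value < t.bi_brevilineal_max else Label.BEEF
        shape = "brevilineal" if label is Label.DAIRY else "longilineal"
        return IndexCall(code, value, label, shape, heuristic=True)
    if code == "LBI":
        label = Label.BEEF if value < t.lbi_compact_max else Label.DAIRY
        shape = "compact/rectangular" if label is Label.BEEF else "leggy"
        return IndexCall(code, value, label, shape, heuristic=True)
    if code == "AI":
        if t.ai_dairy_low <= value <= t.ai_dairy_high:
            return IndexCall(code, value, Label.DAIRY)
        if value < t.ai_dairy_low:
            # low thoracic capacity per stature reads beef-side
            return IndexCall(code, value, Label.BEEF)
        note = "above the dairy band; read with its block"
        return IndexCall(code, value, Label.DUAL, note=note)
    if code == "PI":
        morphology = "brachypelvic" if value < t.pi_brachy_max else "dolichopelvic"
        return IndexCall(code, value, Label.DESCRIPTIVE, morphology)
    if code == "DTI":
        if value > t.dti_beef_min:
            return IndexCall(code, value, Label.BEEF)
        if value < t.dti_dairy_max:
            return IndexCall(code, value, Label.DAIRY)
        return IndexCall(
            code, value, Label.DUAL,
            note=f"between dairy (<{t.dti_dairy_max:g}) and "
                 f"beef (>{t.dti_beef_min:g}) cutoffs",
        )
    if code == "DCI":
        label = Label.DAIRY if value > t.dci_dairy_min else Label.BEEF
        return IndexCall(code, value, label, heuristic=True)
    if code == "TPI":
        label = Label.BEEF if value > t.tpi_beef_min else Label.DAIRY
        return IndexCall(code, value, label)
    if code == "LPI":
        label = Label.BEEF if value > t.lpi_beef_min else Label.DAIRY
        return IndexCall(code, value, label)
    raise KeyError(f"unknown index code {code!r}")


def _vote(call: IndexCall) -> str:
    if call.label is Label.DAIRY:
        return "dairy"
    if call.label is Label.BEEF:
        return "beef"
    # inconclusive label: the index votes with its canonical block
    return "dairy" if call.code in DAIRY_BLOCK else "beef"


def overall_verdict(calls: Mapping[str, IndexCall]) -> tuple[Verdict, int, int]:
    """Majority vote over the nine aptitude-bearing indices."""
    voters = [calls[c] for c in (*DAIRY_BLOCK, *BEEF_BLOCK) if c in calls]
    dairy = sum(1 for call in voters if _vote(call) == "dairy")
    beef = len(voters) - dairy
    if beef == 0 and dairy > 0:
        return Verdict.DAIRY, dairy, beef
    if dairy == 0 and beef > 0:
        return Verdict.BEEF, dairy, beef
    if dairy > beef:
        return Verdict.DUAL_DAIRY_TENDENCY, dairy, beef
    if beef > dairy:
        return Verdict.DUAL_BEEF_TENDENCY, dairy, beef
    return Verdict.DUAL, dairy, beef


def classify_indices(
    indices: IndexVector | Mapping[str, float],
    thresholds: AptitudeThresholds | None = None,
) -> AptitudeProfile:
    """Label every index and derive the overall aptitude verdict."""
    t = thresholds or AptitudeThresholds()
    values = indices.as_dict() if isinstance(indices, IndexVector) else dict(indices)
    calls = {
        code: _classify_one(code, values[code], t)
        for code in INDEX_CODES
        if code in values
    }
    verdict, dairy, beef = overall_verdict(calls)
    return AptitudeProfile(
        calls=calls, verdict=verdict, dairy_votes=dairy, beef_votes=beef
    )


def profile_to_frame(profile: AptitudeProfile):
    """Classification report: one row per index."""
    import pandas as pd

    rows = []
    for code in INDEX_CODES:
        if code not in profile.calls:
            continue
        call = profile.calls[code]
        rows.append({
            "index": code,
            "value": call.value,
            "label": call.label.value,
            "morphology": call.morphology or "",
            "heuristic_threshold": call.heuristic,
            "note": call.note or "",
        })
    return pd.DataFrame(rows)
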