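"""Opinion-change coding from three-scenario questionnaires.

Each subject answers the same three scenarios (travel, murder trial,
vaccination) at three timepoints: T0 (baseline), T1 (after the social-media
session) and T2 (after the in-person discussion).  Per scenario and interval
a binary change code is assigned; the interval score is the sum over
scenarios (0-3); a subject is in the "change" group (C) for an interval iff
the score is >= 1, else "no change" (NC).  The social-media interval
compares T1 against T0; the in-person interval compares T2 against T1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import pandas as pd

__all__ = [
    "TravelAnswer",
    "MurderAnswer",
    "VaccinationAnswer",
    "OpinionRecord",
    "ChangeRules",
    "ChangeCoding",
    "score_scenario_change",
    "aggregate_changes",
    "transition_statistics",
    "chi2_independence",
    "records_to_frame",
    "records_from_frame",
    "QUESTIONNAIRE_COLUMNS",
]

_DESTINATIONS = {"France", "Indonesia"}
_VERDICTS = {"guilty", "not_guilty"}


@dataclass(frozen=True)
class TravelAnswer:
    destination: str
    volunteer: bool
    hours: float

    def __post_init__(self) -> None:
        if self.destination not in _DESTINATIONS:
            raise ValueError(f"destination must be one of {sorted(_DESTINATIONS)}")


@dataclass(frozen=True)
class MurderAnswer:
    verdict: str
    sentence: str

    def __post_init__(self) -> None:
        if self.verdict not in _VERDICTS:
            raise ValueError(f"verdict must be one of {sorted(_VERDICTS)}")


@dataclass(frozen=True)
class VaccinationAnswer:
    vaccinate: bool


@dataclass(frozen=True)
class OpinionRecord:
    """Answers at (T0, T1, T2) for each scenario."""

    subject_id: str
    travel: tuple[TravelAnswer, TravelAnswer, TravelAnswer]
    murder: tuple[MurderAnswer, MurderAnswer, MurderAnswer]
    vaccination: tuple[VaccinationAnswer, VaccinationAnswer, VaccinationAnswer]

    def __post_init__(self) -> None:
        for name in ("travel", "murder", "vaccination"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"{name} must have answers at all three timepoints")


@dataclass(frozen=True)
class ChangeRules:
    """Which sub-rules trigger a travel change (both on by default; the
    underlying coding rule is disjunctive)."""

    volunteer_decision: bool = True
    volunteer_hours: bool = True


def score_scenario_change(pre, post, scenario: str,
                          rules: ChangeRules = ChangeRules()) -> int:
    """Binary change code for one scenario over one interval.

    travel: destination changed OR volunteer decision modified (OR, if
    enabled, offered hours changed); murder: verdict flipped OR sentence
    changed; vaccination: answer differs.
    """
    if scenario == "travel":
        if not isinstance(pre, TravelAnswer) or not isinstance(post, TravelAnswer):
            raise ValueError("travel scoring needs TravelAnswer pre/post")
        changed = pre.destination != post.destination
        if rules.volunteer_decision:
            changed = changed or pre.volunteer != post.volunteer
        if rules.volunteer_hours:
            changed = changed or pre.hours != post.hours
        return int(changed)
    if scenario == "murder":
        if not isinstance(pre, MurderAnswer) or not isinstance(post, MurderAnswer):
            raise ValueError("murder scoring needs MurderAnswer pre/post")
        return int(pre.verdict != post.verdict or pre.sentence != post.sentence)
    if scenario == "vaccination":
        if not isinstance(pre, VaccinationAnswer) or not isinstance(post, VaccinationAnswer):
            raise ValueError("vaccination scoring needs VaccinationAnswer pre/post")
        return int(pre.vaccinate != post.vaccinate)
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass(frozen=True)
class ChangeCoding:
    subject_id: str
    codes_sm: tuple[int, int, int]   # (travel, murder, vaccination), T0 -> T1
    codes_ip: tuple[int, int, int]   # T1 -> T2
    score_sm: int
    score_ip: int
    group_sm: str                    # "C" | "NC"
    group_ip: str


def aggregate_changes(records: list[OpinionRecord],
                      rules: ChangeRules = ChangeRules()) -> list[ChangeCoding]:
    """Per-subject change codes, 0-3 scores, and C/NC groups per interval."""
    if not records:
        raise ValueError("no records to aggregate")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    out = []
    for r in records:
        codes = {}
        for interval, (a, b) in (("sm", (0, 1)), ("ip", (1, 2))):
            codes[interval] = tuple(
                score_scenario_change(getattr(r, sc)[a], getattr(r, sc)[b], sc, rules)
                for sc in ("travel", "murder", "vaccination")
            )
        score_sm, score_ip = sum(codes["sm"]), sum(codes["ip"])
        out.append(
            ChangeCoding(
                subject_id=r.subject_id,
                codes_sm=codes["sm"],
                codes_ip=codes["ip"],
                score_sm=score_sm,
                score_ip=score_ip,
                group_sm="C" if score_sm >= 1 else "NC",
                group_ip="C" if score_ip >= 1 else "NC",
            )
        )
    return out


def _pct(numer: int, denom: int) -> Fraction:
    return Fraction(100 * numer, denom)


def _round1(x: Fraction) -> float:
    """One-decimal half-up rounding of an exact fraction."""
    d = Decimal(x.numerator) / Decimal(x.denominator)
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def transition_statistics(codings: list[ChangeCoding]) -> dict:
    """Percentages of the C/NC groups per interval plus the conditional
    transition percentages (NC_i | NC_s and C_i | C_s), one decimal.

    ``*_exact`` entries are exact :class:`fractions.Fraction` percentages;
    the plain entries are half-up rounded to one decimal.
    """
    if not codings:
        raise ValueError("no codings provided")
    n = len(codings)
    nc_s = sum(c.group_sm == "NC" for c in codings)
    nc_i = sum(c.group_ip == "NC" for c in codings)
    nc_s_and_nc_i = sum(c.group_sm == "NC" and c.group_ip == "NC" for c in codings)
    c_s_and_c_i = sum(c.group_sm == "C" and c.group_ip == "C" for c in codings)
    c_s, c_i = n - nc_s, n - nc_i
    exact = {
        "nc_s_pct": _pct(nc_s, n),
        "c_s_pct": _pct(c_s, n),
        "nc_i_pct": _pct(nc_i, n),
        "c_i_pct": _pct(c_i, n),
        "nc_i_given_nc_s_pct": _pct(nc_s_and_nc_i, nc_s) if nc_s else None,
        "c_i_given_c_s_pct": _pct(c_s_and_c_i, c_s) if c_s else None,
    }
    out: dict = {"n": n, "n_nc_s": nc_s, "n_c_s": c_s, "n_nc_i": nc_i, "n_c_i": c_i}
    for key, val in exact.items():
        out[key] = None if val is None else _round1(val)
        out[key + "_exact"] = val
    return out


def chi2_independence(table, correction: bool = False):
    """Pearson chi-square test of independence on a contingency table.

    Generic utility (no reference contingency table is bundled, so
    this is not tied to any specific reported statistic).
    Returns (chi2, p, dof).
    """
    from scipy.stats import chi2_contingency

    res = chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue), int(res.dof)


# -- delimited-text I/O ------------------------------------------------------

#: Column dictionary for questionnaire tables: one row per subject, answers
#: suffixed by timepoint (t0 = baseline, t1 = post social media, t2 = post
#: discussion).
QUESTIONNAIRE_COLUMNS = tuple(
    ["subject_id"]
    + [
        f"{f}_{tp}"
        for tp in ("t0", "t1", "t2")
        for f in (
            "travel_destination",
            "travel_volunteer",
            "travel_hours",
            "murder_verdict",
            "murder_sentence",
            "vaccinate",
        )
    ]
)


def records_to_frame(records: list[OpinionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {"subject_id": r.subject_id}
        for i, tp in enumerate(("t0", "t1", "t2")):
            row[f"travel_destination_{tp}"] = r.travel[i].destination
            row[f"travel_volunteer_{tp}"] = r.travel[i].volunteer
            row[f"travel_hours_{tp}"] = r.travel[i].hours
            row[f"murder_verdict_{tp}"] = r.murder[i].verdict
            row[f"murder_sentence_{tp}"] = r.murder[i].sentence
            row[f"vaccinate_{tp}"] = r.vaccination[i].vaccinate
        rows.append(row)
    return pd.DataFrame(rows, columns=QUESTIONNAIRE_COLUMNS)


def records_from_frame(frame: pd.DataFrame) -> list[OpinionRecord]:
    missing = set(QUESTIONNAIRE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"questionnaire table missing columns: {sorted(missing)}")

    def _bool(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in ("true", "1", "yes")
        return bool(v)

    records = []
    for _, row in frame.iterrows():
        travel, murder, vacc = [], [], []
        for tp in ("t0", "t1", "t2"):
            travel.append(TravelAnswer(
                destination=str(row[f"travel_destination_{tp}"]),
                volunteer=_bool(row[f"travel_volunteer_{tp}"]),
                hours=float(row[f"travel_hours_{tp}"]),
            ))
            murder.append(MurderAnswer(
                verdict=str(row[f"murder_verdict_{tp}"]),
                sentence=str(row[f"murder_sentence_{tp}"]),
            ))
            vacc.append(VaccinationAnswer(vaccinate=_bool(row[f"vaccinate_{tp}"])))
        records.append(OpinionRecord(
            subject_id=str(row["subject_id"]),
            travel=tuple(travel), murder=tuple(murder), vaccination=tuple(vacc),
        ))
    return records


def codings_to_frame(codings: list[ChangeCoding]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in codings],
            "travel_sm": [c.codes_sm[0] for c in codings],
            "murder_sm": [c.codes_sm[1] for c in codings],
            "vaccination_sm": [c.codes_sm[2] for c in codings],
            "travel_ip": [c.codes_ip[0] for c in codings],
            "murder_ip": [c.codes_ip[1] for c in codings],
            "vaccination_ip": [c.codes_ip[2] for c in codings],
            "score_sm": [c.score_sm for c in codings],
            "score_ip": [c.score_ip for c in codings],
            "group_sm": [c.group_sm for c in codings],
            "group_ip": [c.group_ip for c in codings],
        }
    )
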