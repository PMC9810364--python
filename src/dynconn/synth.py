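"""Synthetic inputs for every pipeline stage.

Three generators are provided:

* label sequences with a controlled per-boundary community switch rate
  (ground truth for flexibility/allegiance/intermittence),
* phase-coupled multichannel signals with planted, time-switching channel
  communities (input to the connectivity + detection stages),
* questionnaire records whose coded opinion-change counts exactly match
  requested marginal counts (input to the behavior stage).

No distributional choice here is a claim about real EEG; everything is a
configurable stand-in with known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .behavior import (
    MurderAnswer,
    OpinionRecord,
    TravelAnswer,
    VaccinationAnswer,
)
from .connectivity import MONTAGE_1020, EegRecording

__all__ = [
    "MembershipSchedule",
    "SyntheticCohort",
    "simulate_label_sequences",
    "simulate_pair_affiliation",
    "simulate_eeg",
    "simulate_questionnaires",
    "simulate_cohort",
    "write_cohort",
]


@dataclass
class MembershipSchedule:
    """Planted community membership: ``labels`` is n_nodes x n_layers."""

    n_nodes: int
    n_layers: int
    labels: np.ndarray
    switch_rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.n_nodes, self.n_layers):
            raise ValueError("labels shape does not match (n_nodes, n_layers)")
        if self.labels.min() < 1:
            raise ValueError("labels must be strictly positive")
        if not 0 <= self.switch_rate <= 1:
            raise ValueError(f"switch_rate must be in [0, 1], got {self.switch_rate}")


@dataclass
class SyntheticCohort:
    """Sessions of one behavioral group across interaction contexts."""

    sessions: list  # of (EegRecording, MembershipSchedule, context)
    group: str      # "C" | "NC"
    seed: int

    def __post_init__(self) -> None:
        if self.group not in ("C", "NC"):
            raise ValueError(f"group must be 'C' or 'NC', got {self.group!r}")
        if self.sessions:
            n_ch = self.sessions[0][0].n_channels
            rate = self.sessions[0][0].rate
            for rec, _, _ in self.sessions:
                if rec.n_channels != n_ch or rec.rate != rate:
                    raise ValueError("all sessions must share channel count and rate")


def simulate_label_sequences(
    n_nodes: int,
    n_layers: int,
    n_communities: int,
    switch_rate: float,
    seed: int,
) -> MembershipSchedule:
    """Markov label sequences: each node resamples its community (uniform over
    the other communities) with probability ``switch_rate`` at each boundary."""
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if not 0 <= switch_rate <= 1:
        raise ValueError(f"switch_rate must be a probability, got {switch_rate}")
    rng = np.random.default_rng(seed)
    labels = np.empty((n_nodes, n_layers), dtype=int)
    labels[:, 0] = rng.integers(1, n_communities + 1, size=n_nodes)
    for t in range(1, n_layers):
        prev = labels[:, t - 1]
        switch = rng.random(n_nodes) < switch_rate
        # uniform over the other communities via a shifted draw
        shift = rng.integers(1, n_communities, size=n_nodes) if n_communities > 1 else np.zeros(n_nodes, int)
        new = (prev - 1 + shift) % n_communities + 1
        labels[:, t] = np.where(switch & (n_communities > 1), new, prev)
    return MembershipSchedule(n_nodes, n_layers, labels, switch_rate)


def simulate_pair_affiliation(a: float, L: int, seed: int) -> np.ndarray:
    """I.i.d. Bernoulli(a) same-community indicator of length L.

    Closed forms for downstream checks: allegiance -> a, and intermittence
    -> 2a(1-a) since P(delta_t != delta_{t+1}) = 2a(1-a).
    """
    if not 0 <= a <= 1:
        raise ValueError(f"a must be a probability, got {a}")
    if L < 2:
        raise ValueError("L must be >= 2")
    rng = np.random.default_rng(seed)
    return (rng.random(L) < a).astype(int)


def _narrowband_source(n: int, rate: float, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS analytic narrowband noise (band-limited random phase)."""
    sos = butter(3, band, btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    x = x / max(np.sqrt(np.mean(x**2)), 1e-30)
    return hilbert(x)


def simulate_eeg(
    schedule: MembershipSchedule,
    rate: float = 256.0,
    window_seconds: float = 10.0,
    band: tuple[float, float] = (8.0, 13.0),
    coupling: float = 0.9,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> EegRecording:
    """Phase-coupled multichannel signal realizing a membership schedule.

    Channels in the same planted community share a band-limited oscillatory
    source; each channel applies its own fixed phase offset (drawn once,
    uniform on [pi/8, 3*pi/8]) so that within-community pairs have a
    consistent nonzero lag, which is what the wPLI rewards.  Membership
    switches are synchronized to window boundaries.  Independent white noise
    at ``noise_sd`` is added throughout.
    """
    if not 0 <= coupling <= 1:
        raise ValueError(f"coupling must be in [0, 1], got {coupling}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    low, high = band
    if not (0 < low < high < rate / 2):
        raise ValueError(f"band {band} must lie inside (0, {rate / 2}) Hz")
    n_per = int(round(window_seconds * rate))
    if n_per < 2:
        raise ValueError("window must contain at least 2 samples")
    rng = np.random.default_rng(seed)
    n_nodes, n_layers = schedule.n_nodes, schedule.n_layers
    n_total = n_layers * n_per
    communities = np.unique(schedule.labels)
    sources = {c: _narrowband_source(n_total, rate, band, rng) for c in communities}
    offsets = rng.uniform(np.pi / 8, 3 * np.pi / 8, size=n_nodes)
    data = noise_sd * rng.standard_normal((n_nodes, n_total))
    phase = np.exp(-1j * offsets)
    for t in range(n_layers):
        sl = slice(t * n_per, (t + 1) * n_per)
        for i in range(n_nodes):
            src = sources[schedule.labels[i, t]][sl]
            data[i, sl] += coupling * np.real(src * phase[i])
    if n_nodes <= len(MONTAGE_1020):
        labels = MONTAGE_1020[:n_nodes]
    else:
        labels = tuple(f"CH{i + 1}" for i in range(n_nodes))
    return EegRecording(labels, rate, data)


_DESTINATIONS = ("France", "Indonesia")
_VERDICTS = ("guilty", "not_guilty")
_SENTENCES = ("10y", "25y", "life", "death")
_HOURS = (0.0, 5.0, 10.0, 20.0)


def _random_answers(rng: np.random.Generator):
    return (
        TravelAnswer(
            destination=_DESTINATIONS[rng.integers(2)],
            volunteer=bool(rng.integers(2)),
            hours=float(_HOURS[rng.integers(len(_HOURS))]),
        ),
        MurderAnswer(
            verdict=_VERDICTS[rng.integers(2)],
            sentence=_SENTENCES[rng.integers(len(_SENTENCES))],
        ),
        VaccinationAnswer(vaccinate=bool(rng.integers(2))),
    )


def _changed_answers(prev, which: np.ndarray, rng: np.random.Generator):
    """Copy of ``prev`` with guaranteed-detectable changes in chosen scenarios."""
    travel, murder, vacc = prev
    if which[0]:
        other = _DESTINATIONS[1 - _DESTINATIONS.index(travel.destination)]
        travel = TravelAnswer(other, travel.volunteer, travel.hours)
    if which[1]:
        other = _VERDICTS[1 - _VERDICTS.index(murder.verdict)]
        murder = MurderAnswer(other, murder.sentence)
    if which[2]:
        vacc = VaccinationAnswer(not vacc.vaccinate)
    return (travel, murder, vacc)


def simulate_questionnaires(
    n_subjects: int,
    marginal_counts: dict[str, int],
    seed: int = 0,
) -> list[OpinionRecord]:
    """Questionnaire records whose coded change counts match the marginals.

    Recognized keys of ``marginal_counts``: ``no_change_after_sm`` (subjects
    with identical T0/T1 answers in all scenarios) and
    ``no_change_after_inperson`` (identical T1/T2).  Unconstrained intervals
    default to half the subjects not changing; unconstrained answer cells are
    filled uniformly at random.
    """
    known = {"no_change_after_sm", "no_change_after_inperson"}
    unknown = set(marginal_counts) - known
    if unknown:
        raise ValueError(f"unrecognized marginal keys: {sorted(unknown)}")
    for key, count in marginal_counts.items():
        if not 0 <= count <= n_subjects:
            raise ValueError(
                f"marginal {key}={count} inconsistent with n_subjects={n_subjects}"
            )
    rng = np.random.default_rng(seed)
    nc_sm = marginal_counts.get("no_change_after_sm", n_subjects // 2)
    nc_ip = marginal_counts.get("no_change_after_inperson", n_subjects // 2)
    nc_sm_mask = np.zeros(n_subjects, dtype=bool)
    nc_sm_mask[rng.permutation(n_subjects)[:nc_sm]] = True
    nc_ip_mask = np.zeros(n_subjects, dtype=bool)
    nc_ip_mask[rng.permutation(n_subjects)[:nc_ip]] = True
    records = []
    for s in range(n_subjects):
        t0 = _random_answers(rng)
        if nc_sm_mask[s]:
            t1 = t0
        else:
            which = np.zeros(3, dtype=bool)
            which[rng.permutation(3)[: rng.integers(1, 4)]] = True
            t1 = _changed_answers(t0, which, rng)
        if nc_ip_mask[s]:
            t2 = t1
        else:
            which = np.zeros(3, dtype=bool)
            which[rng.permutation(3)[: rng.integers(1, 4)]] = True
            t2 = _changed_answers(t1, which, rng)
        records.append(
            OpinionRecord(
                subject_id=f"S{s + 1:03d}",
                travel=(t0[0], t1[0], t2[0]),
                murder=(t0[1], t1[1], t2[1]),
                vaccination=(t0[2], t1[2], t2[2]),
            )
        )
    return records


def simulate_cohort(
    group: str,
    n_subjects: int,
    switch_rate: float,
    contexts: tuple[str, ...] = ("social_media", "in_person"),
    switch_rate_by_context: dict[str, float] | None = None,
    n_nodes: int = 20,
    n_layers: int = 30,
    n_communities: int = 2,
    rate: float = 128.0,
    window_seconds: float = 2.0,
    band: tuple[float, float] = (8.0, 13.0),
    coupling: float = 0.9,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticCohort:
    """One behavioral group's sessions: one (recording, schedule) per subject
    per context.  ``switch_rate_by_context`` overrides the flat rate."""
    ss = np.random.SeedSequence(seed)
    sessions = []
    for s, child in enumerate(ss.spawn(n_subjects)):
        for c, ctx in enumerate(contexts):
            sr = (switch_rate_by_context or {}).get(ctx, switch_rate)
            sub_seed = int(child.generate_state(2)[c])
            sched = simulate_label_sequences(
                n_nodes, n_layers, n_communities, sr, seed=sub_seed
            )
            rec = simulate_eeg(
                sched, rate=rate, window_seconds=window_seconds, band=band,
                coupling=coupling, noise_sd=noise_sd, seed=sub_seed + 1,
            )
            sessions.append((rec, sched, ctx))
    return SyntheticCohort(sessions=sessions, group=group, seed=seed)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 params: dict | None = None) -> Path:
    """Persist a cohort: EDF per session, ground-truth labels as TSV, a
    manifest TSV, and a JSON echo of the generation parameters."""
    from . import edf  # local import: EDF support is an I/O detail

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = ["subject_id\tgroup\tcontext\tedf_path\tlabels_path"]
    per_ctx_counter: dict[str, int] = {}
    for rec, sched, ctx in cohort.sessions:
        idx = per_ctx_counter.get(ctx, 0)
        per_ctx_counter[ctx] = idx + 1
        stem = f"{cohort.group}_{ctx}_{idx + 1:03d}"
        edf_path = outdir / f"{stem}.edf"
        lab_path = outdir / f"{stem}_labels.tsv"
        edf.write_edf(edf_path, rec)
        header = "\t".join(f"layer{t + 1}" for t in range(sched.n_layers))
        np.savetxt(lab_path, sched.labels, fmt="%d", delimiter="\t",
                   header=header, comments="")
        manifest_rows.append(
            f"{cohort.group}{idx + 1:03d}\t{cohort.group}\t{ctx}\t"
            f"{edf_path.name}\t{lab_path.name}"
        )
    manifest = outdir / f"manifest_{cohort.group}.tsv"
    manifest.write_text("\n".join(manifest_rows) + "\n")
    meta = {"group": cohort.group, "seed": cohort.seed,
            "n_sessions": len(cohort.sessions)}
    if params:
        meta["params"] = params
    (outdir / f"metadata_{cohort.group}.json").write_text(
        json.dumps(meta, indent=2) + "\n"
    )
    return manifest
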