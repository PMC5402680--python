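"""Run configuration: a flat, human-editable YAML file with one nesting
level (events, explicit subject/biomarker fields).

Unknown keys are rejected; every defaulted value is logged; all problems in
a file are reported at once in a single :class:`ValidationError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .bbb import DisruptionEvent
from .errors import InvalidInputError, ValidationError
from .physiology import Biomarker, SubjectProfile
from .presets import get_biomarker, get_preset, subject_presets

log = logging.getLogger("neuropk")

_TOP_LEVEL_KEYS = {
    "subject",
    "biomarker",
    "include_skin",
    "events",
    "duration_min",
    "dt_min",
    "brain_leak",
    "bidirectional",
    "outdir",
}
_EVENT_KEYS = {"onset_min", "peak_index", "recovery_tau_min"}

_DEFAULTS = {
    "subject": "adult_male",
    "biomarker": "s100b_monomer",
    "include_skin": False,
    "events": [],
    "duration_min": 1440.0,
    "dt_min": 0.5,
    "brain_leak": None,
    "bidirectional": True,
    "outdir": "neuropk_out",
}


@dataclass
class RunConfig:
    """Fully-resolved configuration for one simulation run."""

    subject: SubjectProfile
    biomarker: Biomarker
    subject_name: str
    biomarker_name: str
    include_skin: bool = False
    events: tuple[DisruptionEvent, ...] = ()
    duration_min: float = 1440.0
    dt_min: float = 0.5
    brain_leak: float | None = None
    bidirectional: bool = True
    outdir: str = "neuropk_out"

    def resolved_echo(self) -> dict:
        """Plain-dict echo of every resolved field (config round-trip)."""
        from dataclasses import asdict

        return {
            "subject": self.subject_name,
            "biomarker": self.biomarker_name,
            "include_skin": self.include_skin,
            "events": [
                {
                    "onset_min": e.onset,
                    "peak_index": e.peak_index,
                    "recovery_tau_min": e.recovery_tau,
                }
                for e in self.events
            ],
            "duration_min": self.duration_min,
            "dt_min": self.dt_min,
            "brain_leak": self.brain_leak,
            "bidirectional": self.bidirectional,
            "outdir": self.outdir,
            "resolved_subject": asdict(self.subject),
            "resolved_biomarker": asdict(self.biomarker),
        }


def _resolve_subject(raw, problems: list[str]) -> tuple[SubjectProfile | None, str]:
    if isinstance(raw, str):
        try:
            return get_preset(raw), raw
        except InvalidInputError as exc:
            problems.append(str(exc))
            return None, raw
    if isinstance(raw, dict):
        known = {f.name for f in dc_fields(SubjectProfile)}
        unknown = set(raw) - known
        if unknown:
            problems.append(f"subject: unknown fields {sorted(unknown)}")
            return None, "<explicit>"
        try:
            return SubjectProfile(**raw), "<explicit>"
        except (InvalidInputError, TypeError) as exc:
            problems.append(f"subject: {exc}")
            return None, "<explicit>"
    problems.append("subject must be a preset name or a mapping of profile fields")
    return None, "<invalid>"


def _resolve_biomarker(raw, problems: list[str]) -> tuple[Biomarker | None, str]:
    if isinstance(raw, str):
        try:
            return get_biomarker(raw), raw
        except InvalidInputError as exc:
            problems.append(str(exc))
            return None, raw
    if isinstance(raw, dict):
        known = {f.name for f in dc_fields(Biomarker)}
        unknown = set(raw) - known
        if unknown:
            problems.append(f"biomarker: unknown fields {sorted(unknown)}")
            return None, "<explicit>"
        try:
            return Biomarker(**raw), "<explicit>"
        except (InvalidInputError, TypeError) as exc:
            problems.append(f"biomarker: {exc}")
            return None, "<explicit>"
    problems.append("biomarker must be a shipped marker name or a mapping of fields")
    return None, "<invalid>"


def _resolve_events(raw, problems: list[str]) -> tuple[DisruptionEvent, ...]:
    events = []
    if not isinstance(raw, list):
        problems.append("events must be a list of {onset_min, peak_index, recovery_tau_min}")
        return ()
    for i, item in enumerate(raw):
        if not isinstance(item, dict):
            problems.append(f"events[{i}] must be a mapping")
            continue
        unknown = set(item) - _EVENT_KEYS
        if unknown:
            problems.append(f"events[{i}]: unknown fields {sorted(unknown)}")
            continue
        missing = _EVENT_KEYS - set(item)
        if missing:
            problems.append(f"events[{i}]: missing fields {sorted(missing)}")
            continue
        try:
            events.append(
                DisruptionEvent(
                    onset=float(item["onset_min"]),
                    peak_index=float(item["peak_index"]),
                    recovery_tau=float(item["recovery_tau_min"]),
                )
            )
        except (InvalidInputError, ValueError) as exc:
            problems.append(f"events[{i}]: {exc}")
    return tuple(events)


def resolve_config(data: dict | None) -> RunConfig:
    """Validate a raw mapping and fill defaults, logging each defaulted key."""
    data = dict(data or {})
    problems: list[str] = []

    unknown = set(data) - _TOP_LEVEL_KEYS
    if unknown:
        problems.append(f"unknown keys {sorted(unknown)}")
        for k in unknown:
            data.pop(k)

    for key, default in _DEFAULTS.items():
        if key not in data:
            data[key] = default
            log.info("config: %s defaulted to %r", key, default)

    subject, subject_name = _resolve_subject(data["subject"], problems)
    biomarker, biomarker_name = _resolve_biomarker(data["biomarker"], problems)
    events = _resolve_events(data["events"], problems)

    for key in ("duration_min", "dt_min"):
        try:
            data[key] = float(data[key])
            if data[key] <= 0:
                problems.append(f"{key} must be > 0, got {data[key]!r}")
        except (TypeError, ValueError):
            problems.append(f"{key} must be a positive number, got {data[key]!r}")
    if data["brain_leak"] is not None:
        try:
            data["brain_leak"] = float(data["brain_leak"])
            if not 0.0 <= data["brain_leak"] <= 100.0:
                problems.append(f"brain_leak must lie in [0,100], got {data['brain_leak']!r}")
        except (TypeError, ValueError):
            problems.append(f"brain_leak must be a number, got {data['brain_leak']!r}")
    if not isinstance(data["include_skin"], bool):
        problems.append("include_skin must be true/false")
    if not isinstance(data["bidirectional"], bool):
        problems.append("bidirectional must be true/false")
    if (
        subject is not None
        and data.get("include_skin") is True
        and subject.age_class == "neonate"
    ):
        problems.append("contradictory fields: skin compartment is not supported for neonates")

    if problems:
        raise ValidationError(problems)

    assert subject is not None and biomarker is not None
    return RunConfig(
        subject=subject,
        biomarker=biomarker,
        subject_name=subject_name,
        biomarker_name=biomarker_name,
        include_skin=bool(data["include_skin"]),
        events=events,
        duration_min=data["duration_min"],
        dt_min=data["dt_min"],
        brain_leak=data["brain_leak"],
        bidirectional=bool(data["bidirectional"]),
        outdir=str(data["outdir"]),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load, validate, and default-fill a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError([f"config file not found: {path}"])
    with path.open("r") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError([f"unparseable config: {exc}"]) from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(["config root must be a mapping"])
    return resolve_config(data)
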