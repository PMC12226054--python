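"""A minimal text dialect of the EyeLink ASC export.

The dialect keeps exactly what the analysis consumes: ``**`` header lines,
``MSG`` event lines (TRIALID n / STIM_ONSET / TONE_ONSET / TRIAL_END) and
whitespace-separated sample lines ``<t> <x> <y> <pupil>``, with a single
``.`` per missing field.  All timestamps are milliseconds on the common
session clock.  Full vendor ASC exports can be down-converted to this
subset by keeping only those line classes.
"""

from __future__ import annotations

from pathlib import Path

from .gaze_synthesis import GazeSample

__all__ = [
    "AscParseError",
    "AscStructureError",
    "write_asc_subset",
    "read_asc_subset",
]

REQUIRED_EVENTS = ("TRIALID", "STIM_ONSET", "TONE_ONSET", "TRIAL_END")


class AscParseError(ValueError):
    """Malformed line; message carries the 1-based line number."""


class AscStructureError(ValueError):
    """Structurally invalid document (e.g. TRIALID without TRIAL_END)."""


def _fmt_t(t: float) -> str:
    return f"{t:.1f}".rstrip("0").rstrip(".")


def write_asc_subset(
    streams: dict[int, list[GazeSample]],
    events: dict[int, dict[str, float]],
    path: str | Path,
    header: dict[str, str] | None = None,
) -> None:
    """Write per-trial samples and events to the ASC-subset dialect.

    ``events[trial]`` must contain ``STIM_ONSET`` and ``TRIAL_END``
    timestamps (``TONE_ONSET`` optional); the TRIALID message is emitted at
    the first sample's timestamp.  Trials are written in index order.
    """
    lines: list[str] = []
    for key, val in (header or {}).items():
        lines.append(f"** {key}: {val}")
    for trial in sorted(streams):
        samples = streams[trial]
        ev = events[trial]
        if not samples:
            raise AscStructureError(f"trial {trial} has no samples")
        lines.append(f"MSG {_fmt_t(samples[0].t)} TRIALID {trial}")
        marks = sorted(
            ((t, lbl) for lbl, t in ev.items() if lbl != "TRIALID"),
            key=lambda p: p[0],
        )
        mi = 0
        for s in samples:
            while mi < len(marks) and marks[mi][0] <= s.t:
                if marks[mi][1] != "TRIAL_END":
                    lines.append(f"MSG {_fmt_t(marks[mi][0])} {marks[mi][1]}")
                mi += 1
            if s.valid:
                lines.append(f"{_fmt_t(s.t)} {s.x:.1f} {s.y:.1f} {s.pupil:.1f}")
            else:
                lines.append(f"{_fmt_t(s.t)} . . .")
        for t, lbl in marks[mi:]:
            if lbl != "TRIAL_END":
                lines.append(f"MSG {_fmt_t(t)} {lbl}")
        end_t = ev.get("TRIAL_END", samples[-1].t)
        lines.append(f"MSG {_fmt_t(end_t)} TRIAL_END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_asc_subset(
    source: str | Path,
) -> tuple[dict[int, list[GazeSample]], dict[int, dict[str, float]]]:
    """Parse the dialect back into per-trial samples and event maps.

    Returns ``(streams, events)`` keyed by trial index; events map label ->
    timestamp (TRIALID at the trial's opening message).  Raises
    ``AscParseError`` with the line number on malformed lines and
    ``AscStructureError`` on unmatched TRIALID/TRIAL_END.
    """
    text = Path(source).read_text() if not hasattr(source, "read") else source.read()
    streams: dict[int, list[GazeSample]] = {}
    events: dict[int, dict[str, float]] = {}
    trial: int | None = None
    last_t = float("-inf")
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        parts = line.split()
        if parts[0] == "MSG":
            if len(parts) < 3:
                raise AscParseError(f"line {ln}: malformed MSG line: {raw!r}")
            try:
                t = float(parts[1])
            except ValueError:
                raise AscParseError(f"line {ln}: bad MSG timestamp: {raw!r}") from None
            if t < last_t:
                raise AscParseError(f"line {ln}: timestamp goes backwards")
            last_t = t
            label = parts[2]
            if label == "TRIALID":
                if trial is not None:
                    raise AscStructureError(
                        f"line {ln}: TRIALID inside unterminated trial {trial}")
                if len(parts) != 4:
                    raise AscParseError(f"line {ln}: TRIALID needs an index")
                trial = int(parts[3])
                streams[trial] = []
                events[trial] = {"TRIALID": t}
            elif label == "TRIAL_END":
                if trial is None:
                    raise AscStructureError(f"line {ln}: TRIAL_END outside a trial")
                events[trial]["TRIAL_END"] = t
                trial = None
            else:
                if trial is None:
                    raise AscStructureError(
                        f"line {ln}: event {label!r} outside a trial")
                events[trial][label] = t
        else:
            if trial is None:
                raise AscStructureError(f"line {ln}: sample outside a trial")
            if len(parts) != 4:
                raise AscParseError(f"line {ln}: sample needs 4 fields: {raw!r}")
            try:
                t = float(parts[0])
            except ValueError:
                raise AscParseError(f"line {ln}: bad sample timestamp") from None
            if t < last_t:
                raise AscParseError(f"line {ln}: timestamp goes backwards")
            last_t = t
            vals = []
            for f in parts[1:]:
                if f == ".":
                    vals.append(float("nan"))
                else:
                    try:
                        vals.append(float(f))
                    except ValueError:
                        raise AscParseError(
                            f"line {ln}: bad sample field {f!r}") from None
            x, y, pupil = vals
            valid = not (x != x or y != y)  # NaN check
            streams[trial].append(GazeSample(t, x, y, 0.0 if pupil != pupil
                                             else pupil, valid))
    if trial is not None:
        raise AscStructureError(f"TRIALID {trial} never closed by TRIAL_END")
    return streams, events
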