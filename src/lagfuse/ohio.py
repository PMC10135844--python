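"""Loader (and fixture writer) for the OhioT1DM XML dialect.

Per-patient XML files carry channels as container elements holding
``<event ts="dd-mm-yyyy HH:MM:SS" .../>`` entries: ``glucose_level``
(attribute ``value``, mg/dL), ``basis_heart_rate`` or ``acceleration``
(``value``; whichever is present serves as the physical activity channel),
``meal`` (``carbs``, grams) and ``bolus`` (``dose``, units; timestamp in
``ts_begin``). The distributed train/test split (``*-ws-training.xml`` /
``*-ws-testing.xml``) is respected: the split time is the first test
glucose timestamp.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from lxml import etree

from .exceptions import CurationError
from .synthetic import RawPatientData

logger = logging.getLogger(__name__)

TS_FORMAT = "%d-%m-%Y %H:%M:%S"

_ACTIVITY_ELEMENTS = ("basis_heart_rate", "acceleration")


def _parse_events(root, element: str, value_attr: str, ts_attrs=("ts", "ts_begin")) -> pd.Series:
    container = root.find(element)
    times, values = [], []
    if container is not None:
        for ev in container.findall("event"):
            ts = next((ev.get(a) for a in ts_attrs if ev.get(a)), None)
            val = ev.get(value_attr)
            if ts is None or val is None:
                continue
            times.append(pd.to_datetime(ts, format=TS_FORMAT))
            values.append(float(val))
    s = pd.Series(values, index=pd.DatetimeIndex(times), dtype=float)
    return s.sort_index()


def _parse_file(path: Path) -> tuple[str, dict[str, pd.Series]]:
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise CurationError(f"malformed XML in {path.name}: {exc}") from exc
    pid = root.get("id") or path.stem.split("-")[0]
    channels = {"bg": _parse_events(root, "glucose_level", "value")}
    activity = pd.Series(dtype=float)
    for el in _ACTIVITY_ELEMENTS:
        s = _parse_events(root, el, "value")
        if len(s):
            activity = s
            break
    if not len(activity):
        logger.warning("%s: no activity element set; channel flagged absent", path.name)
    channels["activity"] = activity
    channels["carbs"] = _parse_events(root, "meal", "carbs")
    channels["bolus"] = _parse_events(root, "bolus", "dose")
    return pid, channels


def load_ohio_xml(directory: str | Path) -> list[RawPatientData]:
    """Load every patient in a directory of OhioT1DM-dialect XML files."""
    directory = Path(directory)
    train_files: dict[str, dict] = {}
    test_files: dict[str, dict] = {}
    for path in sorted(directory.glob("*.xml")):
        pid, channels = _parse_file(path)
        if "testing" in path.name:
            test_files[pid] = channels
        else:
            train_files[pid] = channels
    out = []
    for pid in sorted(train_files):
        tr = train_files[pid]
        te = test_files.get(pid, {c: pd.Series(dtype=float) for c in tr})
        merged = {
            c: pd.concat([s for s in (tr[c], te.get(c)) if s is not None and len(s)])
            .sort_index()
            if len(tr[c]) or len(te.get(c, ())) else tr[c]
            for c in tr
        }
        if pid in test_files and len(te["bg"]):
            split_time = te["bg"].index[0]
        else:
            # no distributed test file: fall back to the last tenth of the record
            idx = merged["bg"].index
            split_time = idx[int(0.9 * len(idx))]
            logger.warning("%s: no testing file; splitting at the last tenth", pid)
        out.append(
            RawPatientData(
                patient_id=pid,
                bg=merged["bg"],
                activity=merged["activity"],
                carbs=merged["carbs"],
                bolus=merged["bolus"],
                split_time=split_time,
            )
        )
    if not out:
        raise CurationError(f"no patient XML files found in {directory}")
    return out


def write_ohio_xml(raw: RawPatientData, directory: str | Path,
                   activity_element: str = "basis_heart_rate") -> tuple[Path, Path]:
    """Write a patient as a training/testing XML file pair (fixture support)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def build(mask_test: bool) -> etree._Element:
        root = etree.Element("patient", id=raw.patient_id)
        sel = (lambda s: s[s.index >= raw.split_time]) if mask_test else (
            lambda s: s[s.index < raw.split_time])
        spec = [
            ("glucose_level", raw.bg, "value", "ts"),
            (activity_element, raw.activity, "value", "ts"),
            ("meal", raw.carbs, "carbs", "ts"),
            ("bolus", raw.bolus, "dose", "ts_begin"),
        ]
        for element, series, value_attr, ts_attr in spec:
            container = etree.SubElement(root, element)
            part = sel(series)
            for ts, val in part.items():
                etree.SubElement(container, "event",
                                 **{ts_attr: ts.strftime(TS_FORMAT), value_attr: f"{val:.10g}"})
        return root

    paths = []
    for suffix, mask_test in (("training", False), ("testing", True)):
        path = directory / f"{raw.patient_id}-ws-{suffix}.xml"
        tree = etree.ElementTree(build(mask_test))
        tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")
        paths.append(path)
    return tuple(paths)
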