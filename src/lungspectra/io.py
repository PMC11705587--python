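"""File formats: FCS 3.1 event tables, CSV signature/matrix dialects,
and JSON sidecars for truth labels and run metadata.

The FCS support is a deliberately minimal, self-contained implementation of
the list-mode float32 subset of FCS 3.1 (HEADER + delimited TEXT segment +
binary DATA segment): enough to round-trip the package's own event tables
and to read simple instrument exports.  Storage is float32 (cytometry
convention); computation elsewhere is float64.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import EventTable
from .spectral import AURORA_5L, DetectorLayout, SpectralSignature

__all__ = [
    "write_fcs",
    "read_fcs",
    "write_event_table",
    "read_event_table",
    "signatures_to_csv",
    "read_signatures_csv",
    "event_table_to_csv",
    "event_table_from_csv",
]

_SCATTER = ("FSC-A", "SSC-A", "FSC-H")
_DELIM = "/"


def _event_frame(table: EventTable) -> pd.DataFrame:
    frame = pd.DataFrame(table.raw, columns=list(table.layout.detector_names))
    for col in _SCATTER:
        frame[col] = table.scatter[col].to_numpy()
    return frame


def write_fcs(table: EventTable, path, extra_keywords: Mapping[str, str] | None = None):
    """Write an event table as a single-dataset FCS 3.1 list-mode file."""
    frame = _event_frame(table)
    data = frame.to_numpy(dtype="<f4")
    n_events, n_par = data.shape
    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$NEXTDATA": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for j, name in enumerate(frame.columns, start=1):
        keywords[f"$P{j}N"] = str(name)
        keywords[f"$P{j}B"] = "32"
        keywords[f"$P{j}E"] = "0,0"
        keywords[f"$P{j}R"] = str(int(max(float(np.nanmax(data[:, j - 1])), 1.0)) + 1)
    if table.seed is not None:
        keywords["#SEED"] = str(table.seed)
    for key, value in (extra_keywords or {}).items():
        keywords[str(key)] = str(value)

    def render_text(begin_data: int, end_data: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        parts = [_DELIM]
        for key, value in kw.items():
            parts.append(f"{key}{_DELIM}{value}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58
    # iterate because the data offsets appear inside the TEXT segment
    begin_data = 0
    end_data = 0
    for _ in range(4):
        text = render_text(begin_data, end_data)
        text_start = header_len
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + data.nbytes - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = render_text(begin_data, end_data)
    text_start = header_len
    text_end = text_start + len(text) - 1
    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{begin_data:>8d}".encode()
        + f"{end_data:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text(segment: bytes) -> dict[str, str]:
    text = segment.decode("ascii", errors="replace")
    delim = text[0]
    fields = text[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2 != 0:
        raise ValueError("FCS TEXT segment has an odd number of fields")
    return {fields[i]: fields[i + 1] for i in range(0, len(fields), 2)}


def read_fcs(path, layout: DetectorLayout | None = AURORA_5L) -> EventTable:
    """Read a float32 list-mode FCS 3.x file into an EventTable.

    When ``layout`` is given, the file must contain every detector channel
    plus the three scatter channels; pass ``layout=None`` to skip the check
    (any channel set is then accepted, detectors inferred by exclusion).
    """
    blob = Path(path).read_bytes()
    if not blob[:6] in (b"FCS3.1", b"FCS3.0"):
        raise ValueError(f"not an FCS 3.x file (offset 0: {blob[:6]!r})")
    try:
        text_start = int(blob[10:18])
        text_end = int(blob[18:26])
    except ValueError as exc:
        raise ValueError("malformed FCS header at offset 10") from exc
    keywords = _parse_text(blob[text_start : text_end + 1])
    begin_data = int(keywords.get("$BEGINDATA") or blob[26:34])
    end_data = int(keywords.get("$ENDDATA") or blob[34:42])
    if keywords.get("$DATATYPE") != "F":
        raise ValueError("only $DATATYPE F (float32) is supported")
    n_par = int(keywords["$PAR"])
    n_events = int(keywords["$TOT"])
    names = [keywords[f"$P{j}N"] for j in range(1, n_par + 1)]
    dtype = "<f4" if keywords.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">f4"
    data = np.frombuffer(blob[begin_data : end_data + 1], dtype=dtype)
    data = data.reshape(n_events, n_par).astype(float)
    frame = pd.DataFrame(data, columns=names)
    missing_scatter = [c for c in _SCATTER if c not in frame.columns]
    if missing_scatter:
        raise ValueError(f"FCS file lacks scatter channels {missing_scatter}")
    if layout is not None:
        missing = [c for c in layout.detector_names if c not in frame.columns]
        if missing:
            raise ValueError(
                f"channel mismatch with layout: {len(missing)} detectors missing "
                f"(first: {missing[:3]})"
            )
        detector_cols = list(layout.detector_names)
    else:
        detector_cols = [c for c in frame.columns if c not in _SCATTER]
        layout = DetectorLayout(lasers=(("CH", len(detector_cols)),))
    seed = keywords.get("#SEED")
    return EventTable(
        raw=frame[detector_cols].to_numpy(dtype=float),
        scatter=frame[list(_SCATTER)].reset_index(drop=True),
        layout=layout,
        seed=int(seed) if seed is not None else None,
    )


def write_event_table(table: EventTable, path) -> None:
    """Write FCS plus a JSON sidecar holding truth labels/abundances & seed."""
    path = Path(path)
    write_fcs(table, path)
    sidecar = {"seed": table.seed}
    if table.truth_labels is not None:
        sidecar["truth_labels"] = [str(x) for x in table.truth_labels]
    if table.truth_abundances is not None:
        sidecar["truth_names"] = list(table.truth_names or ())
        sidecar["truth_abundances"] = table.truth_abundances.tolist()
    path.with_suffix(path.suffix + ".labels.json").write_text(json.dumps(sidecar))


def read_event_table(path, layout: DetectorLayout | None = AURORA_5L) -> EventTable:
    path = Path(path)
    table = read_fcs(path, layout=layout)
    sidecar_path = path.with_suffix(path.suffix + ".labels.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if "truth_labels" in sidecar:
            table.truth_labels = np.asarray(sidecar["truth_labels"], dtype=object)
        if "truth_abundances" in sidecar:
            table.truth_names = tuple(sidecar["truth_names"])
            table.truth_abundances = np.asarray(sidecar["truth_abundances"], dtype=float)
        if sidecar.get("seed") is not None:
            table.seed = int(sidecar["seed"])
    return table


def event_table_to_csv(table: EventTable, path) -> None:
    """CSV mirror of the FCS content (detectors + scatter [+ truth label])."""
    frame = _event_frame(table)
    if table.truth_labels is not None:
        frame["truth_label"] = table.truth_labels
    frame.to_csv(path, index=False, float_format="%.9g")


def event_table_from_csv(path, layout: DetectorLayout = AURORA_5L) -> EventTable:
    frame = pd.read_csv(path)
    labels = None
    if "truth_label" in frame.columns:
        labels = frame.pop("truth_label").to_numpy(dtype=object)
    return EventTable(
        raw=frame[list(layout.detector_names)].to_numpy(dtype=float),
        scatter=frame[list(_SCATTER)].reset_index(drop=True),
        layout=layout,
        truth_labels=labels,
    )


def signatures_to_csv(signatures, path, layout: DetectorLayout = AURORA_5L) -> None:
    """Signature-table dialect: name, peak_intensity, then detector columns."""
    rows = []
    for sig in signatures:
        row = {"name": sig.name, "peak_intensity": sig.peak_intensity}
        row.update(dict(zip(layout.detector_names, sig.values)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_signatures_csv(path, layout: DetectorLayout = AURORA_5L) -> list[SpectralSignature]:
    frame = pd.read_csv(path)
    out = []
    for _, row in frame.iterrows():
        values = row[list(layout.detector_names)].to_numpy(dtype=float)
        out.append(
            SpectralSignature(
                name=str(row["name"]),
                values=values,
                normalization="raw",
                peak_intensity=float(row["peak_intensity"]),
            )
        )
    return out
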