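"""Dataset I/O: a Bruker-style directory dialect and a portable fixture format.

Two dialects are supported:

* **Bruker-style directory** — a directory holding ``ser`` (the pseudo-2D
  FID rows as interleaved real/imaginary values, each row zero-padded to a
  1024-byte boundary) and ``acqus`` (JCAMP-like ``##$KEY= value`` text with
  TD, SW_h, SFO1, BF1, O1, NS, DS, D1, NUC1, BYTORDA, DTYPA).  Payloads may
  be 32-bit integers with an ``NC`` binary scaling exponent (stored * 2**NC
  = actual) or little/big-endian float64.  This dialect carries acquisition
  metadata only; provenance (row order, true log P, relaxation times) is
  not representable and reading it back emits a row-order warning.

* **Fixture format** — ``<stem>.slogp.json`` (schema-versioned header with
  the full acquisition parameters, slice plan and provenance) plus an
  adjacent ``<stem>.slogp.bin`` float64 little-endian payload.  Lossless and
  bit-exact on round trip.

All writers are deterministic byte-for-byte for identical inputs.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from pathlib import Path

import numpy as np

from .errors import DomainError, ParseError
from .geometry import COIL_HALF_LENGTH_DEFAULT, GradientSpec, SlicePlan, get_nucleus
from .processing import LogPResult
from .synth import AcquisitionParams, PseudoSpectrum2D

FIXTURE_SCHEMA = 1
FIXTURE_SUFFIX = ".slogp.json"
PAYLOAD_SUFFIX = ".slogp.bin"

_REQUIRED_ACQUS = (
    "TD", "SW_h", "SFO1", "BF1", "O1", "NS", "DS", "D1", "NUC1", "BYTORDA", "DTYPA",
)


# --------------------------------------------------------------------- acqus

def _format_acqus(pairs: list[tuple[str, object]]) -> str:
    lines = ["##TITLE= slicelogp pseudo-2D dataset", "##JCAMPDX= 5.0"]
    for key, value in pairs:
        if isinstance(value, float):
            value = repr(value)
        lines.append(f"##${key}= {value}")
    lines.append("##END=")
    return "\n".join(lines) + "\n"


def _parse_acqus(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for m in re.finditer(r"^##\$(\w+)=\s*(.*)$", text, re.MULTILINE):
        out[m.group(1)] = m.group(2).strip()
    return out


def _acqus_params(raw: dict[str, str]) -> AcquisitionParams:
    for key in _REQUIRED_ACQUS:
        if key not in raw:
            raise ParseError(f"acqus is missing mandatory key {key!r}", key=key)
    nuc = raw["NUC1"].strip("<>")
    bf1 = float(raw["BF1"])
    o1 = float(raw["O1"])
    sw_h = float(raw["SW_h"])
    try:
        xi = get_nucleus(nuc).xi_ratio
    except DomainError:
        xi = 1.0
    return AcquisitionParams(
        proton_freq=bf1 / xi,
        nucleus=nuc if nuc in ("1H", "19F") else "19F",
        o1p=o1 / bf1,
        sweep_width=sw_h / bf1,
        td=int(raw["TD"]),
        ns=int(raw["NS"]),
        ds=int(raw["DS"]),
        d1=float(raw["D1"]),
    )


# ----------------------------------------------------------------- ser codec

def _interleave(rows: np.ndarray) -> np.ndarray:
    """(n_rows, n) complex -> (n_rows, 2n) float interleaved re/im."""
    out = np.empty((rows.shape[0], rows.shape[1] * 2), dtype=np.float64)
    out[:, 0::2] = rows.real
    out[:, 1::2] = rows.imag
    return out


def _deinterleave(flat: np.ndarray) -> np.ndarray:
    return flat[:, 0::2] + 1j * flat[:, 1::2]


def _pad_bytes(row_bytes: int) -> int:
    return (-row_bytes) % 1024


def _write_ser(path: Path, rows: np.ndarray, dtype: str, byteorder: str) -> int:
    """Write interleaved rows; returns the NC scaling exponent (0 for float)."""
    flat = _interleave(rows)
    nc = 0
    if dtype == "int32":
        peak = float(np.max(np.abs(flat))) if flat.size else 0.0
        if peak > 0:
            # scale so the largest magnitude uses ~30 of the 31 bits;
            # NC may be negative for small float payloads
            nc = int(math.ceil(math.log2(peak / (2**30 - 1))))
        coded = np.round(flat / 2.0**nc).astype("<i4" if byteorder == "little" else ">i4")
    elif dtype == "float64":
        coded = flat.astype("<f8" if byteorder == "little" else ">f8")
    else:
        raise DomainError(f"unsupported ser dtype {dtype!r}")
    itemsize = coded.dtype.itemsize
    with open(path, "wb") as fh:
        for row in coded:
            buf = row.tobytes()
            fh.write(buf)
            fh.write(b"\x00" * _pad_bytes(len(buf)))
    return nc


def _read_ser(path: Path, td: int, dtype: str, byteorder: str, nc: int) -> np.ndarray:
    code = {"int32": "i4", "float64": "f8"}[dtype]
    dt = np.dtype(("<" if byteorder == "little" else ">") + code)
    row_bytes = td * dt.itemsize
    stride = row_bytes + _pad_bytes(row_bytes)
    blob = path.read_bytes()
    if len(blob) % stride:
        raise ParseError(
            f"ser size {len(blob)} is not a whole number of {stride}-byte rows"
        )
    n_rows = len(blob) // stride
    if n_rows < 1:
        raise ParseError("ser holds no rows")
    rows = np.empty((n_rows, td), dtype=np.float64)
    for i in range(n_rows):
        chunk = blob[i * stride : i * stride + row_bytes]
        rows[i] = np.frombuffer(chunk, dtype=dt).astype(np.float64)
    if dtype == "int32":
        rows *= 2.0**nc
    return _deinterleave(rows)


# ------------------------------------------------------------ Bruker dialect

def write_bruker(
    dataset: PseudoSpectrum2D,
    path: str | Path,
    dtype: str = "float64",
    byteorder: str = "little",
) -> Path:
    """Write a Bruker-style directory (``acqus`` + ``ser``)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    p = dataset.params
    bf1 = p.f_spec
    nc = _write_ser(path / "ser", dataset.rows, dtype, byteorder)
    pairs: list[tuple[str, object]] = [
        ("TD", p.td),
        ("SW_h", p.sw_hz),
        ("BF1", bf1),
        ("O1", p.o1p * bf1),
        ("SFO1", bf1 + p.o1p * bf1 * 1e-6),
        ("NS", p.ns),
        ("DS", p.ds),
        ("D1", p.d1),
        ("NUC1", f"<{p.nucleus}>"),
        ("BYTORDA", 0 if byteorder == "little" else 1),
        ("DTYPA", 0 if dtype == "int32" else 2),
        ("NC", nc),
    ]
    (path / "acqus").write_text(_format_acqus(pairs))
    return path


def read_bruker(path: str | Path) -> PseudoSpectrum2D:
    """Read a Bruker-style directory back into a :class:`PseudoSpectrum2D`."""
    path = Path(path)
    acqus = path / "acqus"
    ser = path / "ser"
    if not acqus.exists():
        raise ParseError(f"no acqus file in {path}", key="acqus")
    if not ser.exists():
        raise ParseError(f"no ser file in {path}", key="ser")
    raw = _parse_acqus(acqus.read_text())
    params = _acqus_params(raw)
    dtype = "int32" if int(raw["DTYPA"]) == 0 else "float64"
    byteorder = "little" if int(raw["BYTORDA"]) == 0 else "big"
    rows = _read_ser(ser, params.td, dtype, byteorder, int(raw.get("NC", "0")))
    if rows.shape[0] != 2:
        raise DomainError(
            f"expected a 2-row pseudo-2D ser, found {rows.shape[0]} rows"
        )
    warnings.warn(
        "Bruker-style directory carries no row-order metadata; assuming the "
        "octanol slice is row 1",
        stacklevel=2,
    )
    return PseudoSpectrum2D(rows=rows, params=params, provenance={
        "row_order": "octanol_first", "row_order_assumed": True,
    })


# ----------------------------------------------------------- fixture dialect

def _plan_to_json(plan: SlicePlan | None) -> dict | None:
    return plan.to_dict() if plan is not None else None


def _plan_from_json(d: dict | None) -> SlicePlan | None:
    if d is None:
        return None
    nucleus = get_nucleus(d["nucleus"])
    return SlicePlan(
        nucleus=nucleus,
        gradient=GradientSpec(d["gradient_percent"], d["g_max"]),
        bandwidth=d["bandwidth_hz"],
        offset_upper=d["offset_upper_hz"],
        offset_lower=d["offset_lower_hz"],
        thickness=d["thickness_mm"],
        position_upper=d["position_upper_mm"],
        position_lower=d["position_lower_mm"],
        coil_half_length=d.get("coil_half_length_mm", COIL_HALF_LENGTH_DEFAULT),
        valid=d["valid"],
        messages=tuple(d.get("messages", ())),
    )


_KNOWN_FIXTURE_FIELDS = {"schema_version", "params", "plan", "provenance", "payload"}


def write_fixture(dataset: PseudoSpectrum2D, stem: str | Path) -> Path:
    """Write the portable fixture: ``<stem>.slogp.json`` + ``.slogp.bin``."""
    stem = Path(stem)
    json_path = stem.with_name(stem.name + FIXTURE_SUFFIX)
    bin_path = stem.with_name(stem.name + PAYLOAD_SUFFIX)
    flat = _interleave(dataset.rows).astype("<f8")
    bin_path.write_bytes(flat.tobytes())
    header = {
        "schema_version": FIXTURE_SCHEMA,
        "params": dataset.params.to_dict(),
        "plan": _plan_to_json(dataset.plan),
        "provenance": dataset.provenance,
        "payload": {
            "file": bin_path.name,
            "dtype": "<f8",
            "shape": list(flat.shape),
            "layout": "interleaved-ri",
        },
    }
    json_path.write_text(
        json.dumps(header, sort_keys=True, indent=1, separators=(",", ": ")) + "\n"
    )
    return json_path


def read_fixture(path: str | Path) -> PseudoSpectrum2D:
    path = Path(path)
    header = json.loads(path.read_text())
    unknown = set(header) - _KNOWN_FIXTURE_FIELDS
    if unknown:
        warnings.warn(
            f"fixture header carries unknown fields {sorted(unknown)}; ignored",
            stacklevel=2,
        )
    for key in ("schema_version", "params", "payload"):
        if key not in header:
            raise ParseError(f"fixture header missing {key!r}", key=key)
    payload = header["payload"]
    bin_path = path.with_name(payload["file"])
    flat = np.frombuffer(bin_path.read_bytes(), dtype=payload["dtype"]).reshape(
        payload["shape"]
    )
    params = AcquisitionParams(**header["params"])
    return PseudoSpectrum2D(
        rows=_deinterleave(np.asarray(flat, dtype=np.float64)),
        params=params,
        plan=_plan_from_json(header.get("plan")),
        provenance=header.get("provenance", {}),
    )


# ------------------------------------------------------------------ frontend

def write_dataset(
    dataset: PseudoSpectrum2D,
    path: str | Path,
    dialect: str = "fixture",
    **kwargs,
) -> Path:
    """Write in the requested dialect (``fixture`` or ``bruker``)."""
    if dialect == "fixture":
        return write_fixture(dataset, path)
    if dialect == "bruker":
        return write_bruker(dataset, path, **kwargs)
    raise DomainError(f"unknown dialect {dialect!r}")


def read_dataset(path: str | Path) -> PseudoSpectrum2D:
    """Read a dataset, auto-detecting the dialect from the path layout."""
    path = Path(path)
    if path.is_dir():
        fixtures = sorted(path.glob("*" + FIXTURE_SUFFIX))
        if (path / "acqus").exists() or (path / "ser").exists():
            return read_bruker(path)
        if len(fixtures) == 1:
            return read_fixture(fixtures[0])
        raise ParseError(f"cannot identify a dataset dialect in {path}")
    if path.name.endswith(FIXTURE_SUFFIX):
        return read_fixture(path)
    raise ParseError(f"cannot identify a dataset dialect for {path}")


# -------------------------------------------------------------------- result

RESULT_COLUMNS = (
    "logp", "sigma_logp", "mode", "i_oct", "i_aq", "snr_oct", "snr_aq", "warnings",
)


def write_result(result: LogPResult, path: str | Path, format: str = "json") -> Path:
    """Serialize a quantification record (flat schema, fixed column order).

    JSON keeps the full details block; CSV flattens to one row with the
    fixed :data:`RESULT_COLUMNS` header (warnings joined by ``|``; a missing
    uncertainty serializes as null/empty).
    """
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(result.to_dict(), sort_keys=True, indent=1,
                       separators=(",", ": "), allow_nan=False)
            + "\n"
        )
    elif format == "csv":
        import pandas as pd

        d = result.to_dict()
        row = {k: d[k] for k in RESULT_COLUMNS if k != "warnings"}
        row["warnings"] = "|".join(d["warnings"])
        pd.DataFrame([row], columns=list(RESULT_COLUMNS)).to_csv(path, index=False)
    else:
        raise DomainError(f"unknown result format {format!r}")
    return path


def read_result(path: str | Path) -> dict:
    """Read back a JSON result record as a plain dict."""
    return json.loads(Path(path).read_text())
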