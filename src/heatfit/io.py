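"""Plain-text titration file format (CSV with a ``#`` key:value header).

Layout::

    # format: heatfit-titration-v1
    # V_cell_ul: 202.8
    # T_K: 288.0
    # direction: forward
    # cell_A_uM: 15.0        (likewise cell_B_uM, cell_C_uM)
    # syringe_A_uM: 0.0      (likewise syringe_B_uM, syringe_C_uM)
    injection_index,V_inj_ul,q_ucal
    1,2.0,11.93
    ...

UTF-8, ``.`` decimal separator.  Unknown header keys are preserved on a
read/write round trip (they live in ``TitrationExperiment.meta``).  Units
at this surface are uM, uL and ucal; parsing converts to the internal
molar/litre/cal conventions.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .errors import InvalidDesignError, InvalidParameterError
from .model import (
    UL,
    UM,
    Isotherm,
    TitrationExperiment,
    molar_ratio_for,
    moles_injected_for,
)

FORMAT_TAG = "heatfit-titration-v1"

_REQUIRED_KEYS = (
    "V_cell_ul",
    "T_K",
    "cell_A_uM",
    "cell_B_uM",
    "cell_C_uM",
    "syringe_A_uM",
    "syringe_B_uM",
    "syringe_C_uM",
)
_KNOWN_KEYS = set(_REQUIRED_KEYS) | {"format", "direction"}


def write_titration(
    path: str | Path, experiment: TitrationExperiment, isotherm: Isotherm
) -> None:
    """Serialize a design and its observed/simulated heats."""
    if len(isotherm) != len(experiment.injections):
        raise InvalidParameterError(
            "isotherm length does not match the injection schedule"
        )
    buf = _io.StringIO()
    buf.write(f"# format: {FORMAT_TAG}\n")
    buf.write(f"# V_cell_ul: {experiment.V_cell / UL:.10g}\n")
    buf.write(f"# T_K: {experiment.T:.10g}\n")
    buf.write(f"# direction: {experiment.direction_label}\n")
    for label, comp in (("cell", experiment.cell), ("syringe", experiment.syringe)):
        for tag, value in zip("ABC", comp):
            buf.write(f"# {label}_{tag}_uM: {value / UM:.10g}\n")
    for key, value in experiment.meta.items():
        buf.write(f"# {key}: {value}\n")
    buf.write("injection_index,V_inj_ul,q_ucal\n")
    for i, (v, q) in enumerate(zip(experiment.injections, isotherm.q), start=1):
        buf.write(f"{i},{v / UL:.10g},{q:.10g}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_titration(path: str | Path) -> tuple[TitrationExperiment, Isotherm]:
    """Parse a titration file back into a design and an isotherm.

    Raises informative errors for missing header keys, malformed rows,
    non-monotone injection indices, and non-positive volumes; unknown
    header keys are kept in ``experiment.meta``.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: dict[str, str] = {}
    body_start = None
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            kv = stripped[1:].split(":", 1)
            if len(kv) != 2:
                raise InvalidParameterError(
                    f"{path}: line {lineno}: malformed header line {stripped!r}"
                )
            header[kv[0].strip()] = kv[1].strip()
        else:
            body_start = lineno
            break
    if body_start is None:
        raise InvalidParameterError(f"{path}: no data table found")
    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise InvalidParameterError(
            f"{path}: missing required header key(s): {', '.join(missing)}"
        )

    columns = [c.strip() for c in lines[body_start - 1].split(",")]
    if columns[:3] != ["injection_index", "V_inj_ul", "q_ucal"]:
        raise InvalidParameterError(
            f"{path}: line {body_start}: unexpected table columns {columns}"
        )
    indices, volumes, heats = [], [], []
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            idx = int(parts[0])
            v = float(parts[1])
            q = float(parts[2])
        except (ValueError, IndexError) as exc:
            raise InvalidParameterError(
                f"{path}: line {lineno}: malformed data row {line!r}"
            ) from exc
        if v <= 0:
            raise InvalidParameterError(
                f"{path}: line {lineno}: injection volume must be positive"
            )
        if indices and idx != indices[-1] + 1:
            raise InvalidDesignError(
                f"{path}: line {lineno}: non-monotone injection index {idx}"
            )
        indices.append(idx)
        volumes.append(v)
        heats.append(q)
    if not indices:
        raise InvalidParameterError(f"{path}: data table is empty")

    meta = {k: v for k, v in header.items() if k not in _KNOWN_KEYS}
    experiment = TitrationExperiment(
        cell=tuple(float(header[f"cell_{t}_uM"]) * UM for t in "ABC"),
        syringe=tuple(float(header[f"syringe_{t}_uM"]) * UM for t in "ABC"),
        V_cell=float(header["V_cell_ul"]) * UL,
        injections=tuple(v * UL for v in volumes),
        T=float(header["T_K"]),
        direction_label=header.get("direction", "forward"),
        meta=meta,
    )
    isotherm = Isotherm(
        q=np.asarray(heats),
        molar_ratio=molar_ratio_for(experiment),
        moles_injected=moles_injected_for(experiment),
    )
    return experiment, isotherm
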