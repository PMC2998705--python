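"""Plain-text serialization of fitted calibration models.

A flat ``key = value`` document; vector-valued fields are comma-separated in
gene order.  Floats are written with ``repr`` (17 significant digits), so a
write→read round trip reproduces every number exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .calibrate import CalibrationModel, RedundancyModel
from .errors import InputError

FORMAT_TAG = "agegrade-model-v1"


def write_model(model: CalibrationModel, path: str | Path) -> None:
    red = model.redundancy
    lines = [
        f"format = {FORMAT_TAG}",
        f"sex = {model.sex_label or ''}",
        f"n = {model.n}",
        f"alpha = {model.alpha!r}",
        f"beta = {model.beta!r}",
        f"r_squared = {model.r_squared!r}",
        f"canonical_correlation = {red.canonical_correlation!r}",
        f"genes = {','.join(red.gene_ids)}",
        f"mu = {','.join(repr(float(v)) for v in red.mu)}",
        f"sd = {','.join(repr(float(v)) for v in red.sd)}",
        f"weights = {','.join(repr(float(v)) for v in red.weights)}",
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_model(path: str | Path) -> CalibrationModel:
    fields: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InputError(f"{path}: line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    if fields.get("format") != FORMAT_TAG:
        raise InputError(f"{path}: not a {FORMAT_TAG} file")
    try:
        gene_ids = tuple(fields["genes"].split(","))
        red = RedundancyModel(
            gene_ids=gene_ids,
            mu=np.array([float(v) for v in fields["mu"].split(",")]),
            sd=np.array([float(v) for v in fields["sd"].split(",")]),
            weights=np.array([float(v) for v in fields["weights"].split(",")]),
            canonical_correlation=float(fields["canonical_correlation"]),
        )
        return CalibrationModel(
            redundancy=red,
            alpha=float(fields["alpha"]),
            beta=float(fields["beta"]),
            r_squared=float(fields["r_squared"]),
            n=int(fields["n"]),
            sex_label=fields.get("sex") or None,
        )
    except (KeyError, ValueError) as exc:
        raise InputError(f"{path}: malformed model file ({exc})") from exc
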