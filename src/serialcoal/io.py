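"""Config parsing and delimited-text serialization.

Model configs are YAML (JSON works too): top-level ``demes``,
optional ``deme_labels``, and a list of ``epochs`` each carrying
``t_start``, ``t_end`` ("inf" accepted), exactly one of
``adjacency`` / ``laplacian``, and exactly one of ``gamma`` /
``Ne`` (+ ``ploidy_scaling``, default 2, giving
``gamma = 1 / (ploidy_scaling * Ne)``).

Matrices travel as whitespace-delimited text with ``# key: value`` header
lines; values are written with 17 significant digits so round-trips are
bitwise-exact, and missing cells (vacant demes) are the string ``nan``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .branch_mean import MeanMatrix
from .branch_pdf import PdfGrid
from .demography import DemographicModel, EpochParams, validate_model
from .lpsc import SurvivalMatrix

__all__ = [
    "read_model",
    "write_mean_matrix",
    "read_mean_matrix",
    "write_survival_matrix",
    "read_survival_matrix",
    "write_pdf_grid",
    "read_pdf_grid",
    "write_matrices",
    "read_matrices",
    "read_samples",
    "write_samples",
]


def _parse_time(v) -> float:
    if isinstance(v, str) and v.strip().lower() in {"inf", "+inf", "infinity"}:
        return math.inf
    return float(v)


def read_model(path) -> DemographicModel:
    """Parse and validate a model config; raise on violations."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "epochs" not in cfg:
        raise ValueError(f"{path}: config must define an 'epochs' list")
    d = int(cfg.get("demes", 0))
    epochs = []
    for k, ec in enumerate(cfg["epochs"]):
        has_adj, has_lap = "adjacency" in ec, "laplacian" in ec
        if has_adj and has_lap:
            raise ValueError(
                f"epoch {k}: ambiguous specification — give adjacency or "
                "laplacian, not both"
            )
        if not (has_adj or has_lap):
            raise ValueError(f"epoch {k}: needs adjacency or laplacian")
        if "gamma" in ec and "Ne" in ec:
            raise ValueError(
                f"epoch {k}: ambiguous specification — give gamma or Ne, not both"
            )
        if "gamma" in ec:
            gamma = np.asarray(ec["gamma"], dtype=float)
        elif "Ne" in ec:
            scale = float(ec.get("ploidy_scaling", 2.0))
            gamma = 1.0 / (scale * np.asarray(ec["Ne"], dtype=float))
        else:
            raise ValueError(f"epoch {k}: needs gamma or Ne")
        t0, t1 = _parse_time(ec["t_start"]), _parse_time(ec["t_end"])
        if has_adj:
            ep = EpochParams(t0, t1, np.asarray(ec["adjacency"], float), gamma)
        else:
            ep = EpochParams.from_laplacian(
                t0, t1, np.asarray(ec["laplacian"], float), gamma
            )
        epochs.append(ep)
    model = DemographicModel(epochs=epochs, deme_labels=cfg.get("deme_labels"))
    if d and model.d != d:
        raise ValueError(f"config says demes={d} but matrices are {model.d}-dim")
    issues = validate_model(model)
    if issues:
        raise ValueError("invalid model: " + "; ".join(issues))
    return model


def _write_headers(fh, headers: dict) -> None:
    for k, v in headers.items():
        fh.write(f"# {k}: {v}\n")


def _read_headers(path) -> tuple[dict, list[str]]:
    headers: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                headers[key.strip()] = val.strip()
            else:
                body.append(line)
    return headers, body


def _fmt_matrix(fh, B: np.ndarray) -> None:
    for row in B:
        fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def _parse_matrix(body: list[str], d: int, path) -> np.ndarray:
    rows = [[float(v) for v in line.split()] for line in body]
    B = np.array(rows, dtype=float)
    if B.shape != (d, d):
        raise ValueError(f"{path}: header says d={d} but body is {B.shape}")
    return B


def write_mean_matrix(path, mm: MeanMatrix) -> None:
    with open(path, "w") as fh:
        _write_headers(fh, {"kind": "mean", "x": mm.x, "y": mm.y, "d": mm.d})
        _fmt_matrix(fh, mm.B)


def read_mean_matrix(path) -> MeanMatrix:
    headers, body = _read_headers(path)
    if headers.get("kind") != "mean":
        raise ValueError(f"{path}: not a mean-matrix file")
    d = int(headers["d"])
    return MeanMatrix(
        x=float(headers["x"]), y=float(headers["y"]), B=_parse_matrix(body, d, path)
    )


def write_survival_matrix(path, sm: SurvivalMatrix) -> None:
    with open(path, "w") as fh:
        _write_headers(
            fh,
            {"kind": "survival", "x": sm.x, "y": sm.y, "r": sm.r, "mu": sm.mu, "d": sm.d},
        )
        _fmt_matrix(fh, sm.rho)


def read_survival_matrix(path) -> SurvivalMatrix:
    headers, body = _read_headers(path)
    if headers.get("kind") != "survival":
        raise ValueError(f"{path}: not a survival-matrix file")
    d = int(headers["d"])
    return SurvivalMatrix(
        x=float(headers["x"]),
        y=float(headers["y"]),
        r=float(headers["r"]),
        mu=float(headers["mu"]),
        rho=_parse_matrix(body, d, path),
    )


def write_pdf_grid(path, f: PdfGrid) -> None:
    """Long-format density dump: one (i, j, b, density) row per grid point.

    The analytic tail and jump left-limits are in-memory constructs and are
    not serialized; a written grid reloads as a plain truncated density.
    """
    d = f.d
    with open(path, "w") as fh:
        _write_headers(
            fh, {"kind": "pdf", "x": f.x, "y": f.y, "db": f.db, "offset": f.offset, "d": d}
        )
        fh.write("i j b density\n")
        b = f.b_grid
        for k in range(f.K + 1):
            for i in range(d):
                for j in range(d):
                    fh.write(f"{i} {j} {b[k]:.17g} {f.values[k, i, j]:.17g}\n")


def read_pdf_grid(path) -> PdfGrid:
    headers, body = _read_headers(path)
    if headers.get("kind") != "pdf":
        raise ValueError(f"{path}: not a pdf-grid file")
    d = int(headers["d"])
    x, y, db = (float(headers[k]) for k in ("x", "y", "db"))
    offset = float(headers["offset"])
    rows = body[1:]  # skip column header
    K = len(rows) // (d * d) - 1
    values = np.zeros((K + 1, d, d))
    for line in rows:
        si, sj, sb, sv = line.split()
        k = int(round((float(sb) - offset) / db))
        values[k, int(si), int(sj)] = float(sv)
    return PdfGrid(x=x, y=y, db=db, values=values)


_WRITERS = {"mean": write_mean_matrix, "survival": write_survival_matrix, "pdf": write_pdf_grid}
_READERS = {"mean": read_mean_matrix, "survival": read_survival_matrix, "pdf": read_pdf_grid}


def write_matrices(path, obj, kind: str) -> None:
    try:
        _WRITERS[kind](path, obj)
    except KeyError:
        raise ValueError(f"unknown kind {kind!r}") from None


def read_matrices(path, kind: str):
    try:
        return _READERS[kind](path)
    except KeyError:
        raise ValueError(f"unknown kind {kind!r}") from None


def write_samples(path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
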