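"""File formats: ASCII curves, SasView-style .dat, model configs, PDB.

Curve files are plain whitespace-separated columns with ``#`` comment
headers, written at 8 significant digits so they re-parse to the in-memory
arrays exactly at that precision.  Simulated data use the de-facto
3-column (q, I, σ) format read by SAXS fitting tools.

Model specifications round-trip through a flat key-value block format;
floats are serialized with ``repr`` (shortest exact representation), so
write → read → write is byte-identical.

The 3-D bead model is exported as fixed-column PDB: one ATOM record per
point, element chosen by contrast sign (C for Δρ>0, O for Δρ<0, N for
Δρ=0), occupancy carrying the normalized |Δρ|.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, PDBExportError
from .noise import SimulatedData
from .pairdist import PairDistribution, ScatteringCurve
from .subunits import ModelSpec, PointCloud, Subunit

__all__ = [
    "write_columns",
    "read_columns",
    "write_pr",
    "write_iq",
    "write_seff",
    "write_simulated_data",
    "read_simulated_data",
    "write_model_spec",
    "read_model_spec",
    "model_spec_to_text",
    "model_spec_from_text",
    "write_pdb",
]

_FLOAT_FMT = "%.8e"


def write_columns(path, columns, header: str = "") -> None:
    """Write equal-length 1-D arrays as whitespace-separated ASCII columns."""
    arr = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    np.savetxt(path, arr, fmt=_FLOAT_FMT, header=header)


def read_columns(path) -> np.ndarray:
    """Read an ASCII column file back; returns shape (n_rows, n_cols)."""
    return np.atleast_2d(np.loadtxt(path, comments="#"))


def write_pr(path, pd: PairDistribution) -> None:
    """p(r) as 2 columns (r [Å], p normalized to max |p| = 1, leading 0,0)."""
    r, p = pd.export_arrays()
    write_columns(path, (r, p), header="r [AA]  p(r) (max-normalized)")


def write_iq(path, curve: ScatteringCurve) -> None:
    """I(q) as 2 columns (q [Å⁻¹], I)."""
    write_columns(path, (curve.q, curve.I), header="q [1/AA]  I(q) (I(0)=1)")


def write_seff(path, curve: ScatteringCurve) -> None:
    """Effective structure factor as 2 columns (q [Å⁻¹], S_eff)."""
    write_columns(path, (curve.q, curve.S_eff), header="q [1/AA]  S_eff(q)")


def write_simulated_data(path, data: SimulatedData) -> None:
    """Simulated data as 3 columns (q, I_sim, σ) — SasView-compatible .dat."""
    write_columns(
        path,
        (data.q, data.i_sim, data.sigma),
        header=(
            "simulated small-angle scattering data\n"
            f"noise scale = {data.noise_scale!r}, seed = {data.seed}\n"
            "q [1/AA]  I_sim  sigma"
        ),
    )


def read_simulated_data(path) -> SimulatedData:
    """Read a 3-column (q, I, σ) file into a :class:`SimulatedData`."""
    arr = read_columns(path)
    if arr.shape[1] < 3:
        raise InvalidParameterError(f"{path}: expected 3 columns (q, I, sigma)")
    return SimulatedData(q=arr[:, 0], i_sim=arr[:, 1], sigma=arr[:, 2])


# ---------------------------------------------------------------------------
# model-spec config files


def _fmt(value: float) -> str:
    return repr(float(value))


def model_spec_to_text(spec: ModelSpec) -> str:
    lines = [
        "[model]",
        f"exclude_overlap = {'true' if spec.exclude_overlap else 'false'}",
        f"n_points = {spec.n_points_total}",
        f"seed = {spec.seed}",
    ]
    for sub in spec.subunits:
        lines += [
            "",
            "[subunit]",
            f"kind = {sub.kind}",
            f"dims = {' '.join(_fmt(d) for d in sub.dims)}",
            f"contrast = {_fmt(sub.contrast)}",
            f"com = {' '.join(_fmt(c) for c in sub.com)}",
        ]
    return "\n".join(lines) + "\n"


def model_spec_from_text(text: str) -> ModelSpec:
    model_kv: dict[str, str] = {}
    subunit_blocks: list[dict[str, str]] = []
    current: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[model]":
            current = model_kv
        elif line == "[subunit]":
            current = {}
            subunit_blocks.append(current)
        elif "=" in line:
            if current is None:
                raise InvalidParameterError("key-value pair outside any block")
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
        else:
            raise InvalidParameterError(f"cannot parse config line: {raw!r}")
    if not subunit_blocks:
        raise InvalidParameterError("model config contains no [subunit] blocks")
    subunits = []
    for block in subunit_blocks:
        subunits.append(
            Subunit(
                kind=block["kind"],
                dims=tuple(float(v) for v in block["dims"].split()),
                contrast=float(block.get("contrast", "1.0")),
                com=tuple(float(v) for v in block.get("com", "0 0 0").split()),
            )
        )
    return ModelSpec(
        subunits=tuple(subunits),
        exclude_overlap=model_kv.get("exclude_overlap", "true") == "true",
        n_points_total=int(model_kv.get("n_points", "5000")),
        seed=int(model_kv.get("seed", "0")),
    )


def write_model_spec(path, spec: ModelSpec) -> None:
    Path(path).write_text(model_spec_to_text(spec))


def read_model_spec(path) -> ModelSpec:
    return model_spec_from_text(Path(path).read_text())


# ---------------------------------------------------------------------------
# PDB export


def write_pdb(cloud: PointCloud, path) -> None:
    """One ATOM record per bead, fixed-column PDB dialect.

    Element by contrast sign (C: Δρ>0, O: Δρ<0, N: Δρ=0); occupancy is the
    normalized |Δρ| of the owning subunit.  Coordinates must fit the fixed
    8.3f columns, i.e. |coord| < 10⁴ Å.
    """
    if len(cloud) == 0:
        raise PDBExportError("cannot export an empty point cloud")
    if np.any(np.abs(cloud.positions) >= 1e4):
        raise PDBExportError(
            "coordinates overflow the fixed PDB columns (|coord| >= 1e4 Å); "
            "scale the model down before export"
        )
    peak = float(np.abs(cloud.weights).max())
    occ = np.abs(cloud.weights) / peak if peak > 0 else np.zeros(len(cloud))
    with open(path, "w") as fh:
        for i, (pos, w, o) in enumerate(zip(cloud.positions, cloud.weights, occ)):
            element = "C" if w > 0 else ("O" if w < 0 else "N")
            serial = (i + 1) % 100000
            resseq = (i + 1) % 10000
            fh.write(
                f"ATOM  {serial:5d} {element:>2s}   BEA A{resseq:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{o:6.2f}{0.0:6.2f}"
                f"          {element:>2s}\n"
            )
        fh.write("END\n")
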