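"""File formats and run configuration.

Reads C-alpha coordinates from minimal PDB files (via biotite), stores
reference paths as multi-model PDB plus a YAML sidecar (lambda, selections,
spacing), and speaks the PLUMED-style COLVAR/HILLS ASCII dialects.  All
writers emit comment headers stating the units (nm, nm^2, ps, kJ/mol);
numeric columns are printed with %.6f so write -> read round-trips to the
printed precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import Configuration
from .metad import BiasState, Hill, WallRestraint
from .pathcv import ReferencePath
from .fes import Axis, FESGrid
from .trace import CVTrace

logger = logging.getLogger("pathmetad")

__all__ = [
    "read_pdb_ca",
    "parse_residue_ranges",
    "write_path_pdb",
    "read_path_pdb",
    "write_colvar",
    "read_colvar",
    "write_hills",
    "read_hills",
    "write_fes",
    "read_fes",
    "write_xyz",
    "read_xyz",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# PDB


def parse_residue_ranges(spec) -> list[tuple[int, int]]:
    """Parse '1-29,68-117,161-214' (1-based, inclusive) into range tuples."""
    if isinstance(spec, (list, tuple)):
        return [(int(a), int(b)) for a, b in spec]
    ranges = []
    for part in str(spec).split(","):
        part = part.strip()
        if "-" in part[1:]:
            a, b = part.rsplit("-", 1)
            ranges.append((int(a), int(b)))
        else:
            ranges.append((int(part), int(part)))
    return ranges


def read_pdb_ca(path, selections=None, model: int = 1) -> Configuration:
    """C-alpha configuration from a PDB file, coordinates converted to nm.

    ``selections`` maps names to residue-range specs (1-based, e.g.
    ``{"LID": "118-160"}``); the returned configuration carries them as
    0-based index sets.  Multi-model files yield the first model by default.
    Altloc records other than blank/'A' are ignored with a logged warning.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=model, altloc="all",
                            extra_fields=["occupancy"])
    try:
        altloc = pdb.get_structure(model=model, altloc="all",
                                   extra_fields=["altloc_id"]).altloc_id
    except Exception:
        altloc = np.array([""] * arr.array_length())
    keep = np.isin(altloc, ["", " ", "A"])
    if not keep.all():
        logger.warning("ignoring %d atoms with altloc other than blank/'A'",
                       int((~keep).sum()))
    arr = arr[keep]
    ca = arr[arr.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"no C-alpha atoms found in {path}")
    res_ids = ca.res_id
    coords = ca.coord / 10.0  # Angstrom -> nm
    labels = [str(int(r)) for r in res_ids]

    sels = {}
    if selections:
        for name, spec in selections.items():
            ranges = parse_residue_ranges(spec)
            idx, missing = [], []
            for lo, hi in ranges:
                for rid in range(lo, hi + 1):
                    hits = np.flatnonzero(res_ids == rid)
                    if hits.size == 0:
                        missing.append(rid)
                    else:
                        idx.append(int(hits[0]))
            if missing:
                raise ValueError(
                    f"selection {name!r}: residues missing a C-alpha: {missing}")
            sels[name] = np.array(sorted(idx))
    return Configuration(coords, labels, sels)


def _beads_to_atom_array(cfg: Configuration, coords_nm: np.ndarray):
    import biotite.structure as struc

    n = cfg.n_particles
    arr = struc.AtomArray(n)
    arr.coord = coords_nm * 10.0
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["GLY"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    return arr


def write_path_pdb(path_obj: ReferencePath, filename):
    """Reference path as multi-model PDB + YAML sidecar (lambda, selections)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    template = path_obj.frames[0]
    arrays = [_beads_to_atom_array(template, f.coords) for f in path_obj.frames]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(filename))
    meta = {
        "lambda_nm^-2": float(path_obj.lam),
        "align_idx": [int(i) for i in path_obj.align_idx],
        "measure_idx": [int(i) for i in path_obj.measure_idx],
        "spacing_nm^2": [float(x) for x in path_obj.spacing],
        "labels": list(template.labels),
        "selections": {k: [int(i) for i in v]
                       for k, v in template.selections.items()},
    }
    with open(str(filename) + ".meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_path_pdb(filename) -> ReferencePath:
    """Read a reference path written by :func:`write_path_pdb`."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(filename))
    stack = pdb.get_structure()
    with open(str(filename) + ".meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    sels = {k: np.array(v) for k, v in meta.get("selections", {}).items()}
    labels = meta.get("labels")
    frames = [Configuration(stack.coord[i] / 10.0, list(labels), sels)
              for i in range(stack.stack_depth())]
    return ReferencePath(frames, meta["lambda_nm^-2"],
                         np.array(meta["align_idx"]),
                         np.array(meta["measure_idx"]),
                         np.array(meta["spacing_nm^2"]))


# ---------------------------------------------------------------------------
# COLVAR / HILLS dialect


def _parse_fields_header(line, what):
    if not line.startswith("#! FIELDS"):
        raise ValueError(f"{what}: missing '#! FIELDS' header")
    return line.split()[2:]


def write_colvar(trace: CVTrace, filename):
    """COLVAR record stream: '#! FIELDS time <cvs...> bias', one row per record."""
    with open(filename, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(trace.names) + " bias\n")
        fh.write("# units: time ps, path CVs s dimensionless / z nm^2, bias kJ/mol\n")
        for i in range(len(trace)):
            row = [trace.times[i], *trace.values[i], trace.bias_energy[i]]
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_colvar(filename) -> CVTrace:
    """Read a COLVAR file; column order is taken from the header, aux columns kept."""
    with open(filename) as fh:
        lines = fh.readlines()
    fields = _parse_fields_header(lines[0], "COLVAR")
    if fields[0] != "time" or fields[-1] != "bias":
        raise ValueError("COLVAR: expected 'time' first and 'bias' last in FIELDS")
    names = fields[1:-1]
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise ValueError(f"COLVAR line {ln}: expected {len(fields)} columns, "
                             f"got {len(parts)}")
        rows.append([float(x) for x in parts])
    data = np.array(rows)
    return CVTrace(times=data[:, 0], names=names, values=data[:, 1:-1],
                   bias_energy=data[:, -1])


def write_hills(bias: BiasState, filename):
    """HILLS file, PLUMED-style: time, center, sigma, height, bias factor."""
    cvs = bias.biased_cv_ids
    cols = ["time"] + [f"center_{c}" for c in cvs] + [f"sigma_{c}" for c in cvs] \
        + ["height", "biasf"]
    with open(filename, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        fh.write(f"#! SET temperature {bias.T:.6f}\n")
        fh.write(f"#! SET pace {bias.pace:.6f}\n")
        fh.write(f"#! SET w0 {bias.w0:.6f}\n")
        fh.write("# units: time ps, heights kJ/mol\n")
        for h in bias.hills:
            row = [h.time, *h.center, *h.sigma, h.height, bias.gamma]
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_hills(filename, temperature: float | None = None) -> BiasState:
    """Read a HILLS file back into a BiasState.

    deltaT is reconstructed from the bias factor; temperature, pace and w0
    come from '#! SET' lines when present (temperature may be overridden).
    """
    with open(filename) as fh:
        lines = fh.readlines()
    fields = _parse_fields_header(lines[0], "HILLS")
    known_prefixes = ("time", "center_", "sigma_", "height", "biasf")
    for f in fields:
        if not any(f == p or f.startswith(p) for p in known_prefixes):
            raise ValueError(f"HILLS: unknown field {f!r}")
    cv_ids = [f[len("center_"):] for f in fields if f.startswith("center_")]
    k = len(cv_ids)
    meta = {}
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if line.startswith("#! SET"):
            _, _, key, val = line.split()
            meta[key] = float(val)
            continue
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise ValueError(f"HILLS line {ln}: expected {len(fields)} columns, "
                             f"got {len(parts)}")
        rows.append([float(x) for x in parts])
    T = temperature if temperature is not None else meta.get("temperature", 300.0)
    if rows:
        biasf = rows[0][-1]
    else:
        biasf = 12.0
    deltaT = T * (biasf - 1.0)
    hills = [Hill(center=np.array(r[1:1 + k]), sigma=np.array(r[1 + k:1 + 2 * k]),
                  height=r[1 + 2 * k], time=r[0]) for r in rows]
    pace = meta.get("pace", float(np.median(np.diff([h.time for h in hills])))
                    if len(hills) > 1 else 1.0)
    w0 = meta.get("w0", hills[0].height if hills else 1.0)
    sigma = hills[0].sigma if hills else np.ones(k)
    return BiasState(T=T, deltaT=deltaT, pace=pace, w0=w0, sigma=sigma,
                     biased_cv_ids=cv_ids, hills=hills)


# ---------------------------------------------------------------------------
# FES blocks and XYZ


def write_fes(fes: FESGrid, filename):
    """FES as whitespace-delimited 'x [y] F' blocks (kJ/mol), gnuplot-style."""
    with open(filename, "w") as fh:
        fh.write("# free-energy surface, kJ/mol; unvisited cells are nan\n")
        for ax in fes.axes:
            fh.write(f"# axis {ax.label or 'cv'} {ax.lo:.6f} {ax.hi:.6f} {ax.n}\n")
        if len(fes.axes) == 1:
            for x, f in zip(fes.axes[0].centers(), fes.values):
                fh.write(f"{x:.6f} {f:.6f}\n")
        elif len(fes.axes) == 2:
            xs, ys = fes.axes[0].centers(), fes.axes[1].centers()
            for i, x in enumerate(xs):
                for j, y in enumerate(ys):
                    fh.write(f"{x:.6f} {y:.6f} {fes.values[i, j]:.6f}\n")
                fh.write("\n")
        else:
            raise ValueError("FES text export supports 1-D and 2-D grids")


def read_fes(filename) -> FESGrid:
    axes = []
    data = []
    with open(filename) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# axis"):
                _, _, label, lo, hi, n = line.split()
                axes.append(Axis(float(lo), float(hi), int(n), label))
            elif line and not line.startswith("#"):
                data.append(float(line.split()[-1]))
    shape = tuple(ax.n for ax in axes)
    return FESGrid(axes, np.array(data).reshape(shape))


def write_xyz(traj, labels, times, filename):
    """Trajectory as XYZ; coordinates in nm, comment line carries time in ps."""
    traj = np.asarray(traj)
    with open(filename, "w") as fh:
        for frame, t in zip(traj, times):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(f"t= {t:.6f} ps (coordinates in nm)\n")
            for lbl, xyz in zip(labels, frame):
                el = "".join(ch for ch in str(lbl) if ch.isalpha())[:2] or "C"
                fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def read_xyz(filename):
    frames, times = [], []
    with open(filename) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        t = float(comment.split()[1]) if "t=" in comment else float(len(times))
        coords = [list(map(float, lines[i + 2 + j].split()[1:4])) for j in range(n)]
        frames.append(coords)
        times.append(t)
        i += 2 + n
    return np.array(frames), np.array(times)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Structured run settings with production-style defaults.

    Defaults: T = 300 K, deltaT = 3300 K, pace 2 ps, w0 = 2 kJ/mol,
    sigma_s = 0.03 (s-units under the s in [1, P] convention), upper wall on
    z at 1 nm^2 with spring 1000 kJ/mol/nm^4.  Every stochastic command
    requires an explicit seed.
    """

    system: dict = field(default_factory=dict)
    path: dict = field(default_factory=dict)
    bias: dict = field(default_factory=dict)
    run: dict = field(default_factory=dict)
    output: str = "."

    DEFAULT_BIAS = {"temperature": 300.0, "delta_t": 3300.0, "pace_ps": 2.0,
                    "w0_kj": 2.0, "sigma_s": 0.03, "wall_z_threshold": 1.0,
                    "wall_z_spring": 1000.0}
    DEFAULT_PATH = {"n_frames": 20, "rel_tol": 0.02}
    DEFAULT_RUN = {"timestep_ps": 0.005, "friction_ps": 5.0,
                   "record_every": 10}

    @classmethod
    def load(cls, filename) -> "RunConfig":
        with open(filename) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(system=raw.get("system", {}), path=raw.get("path", {}),
                  bias=raw.get("bias", {}), run=raw.get("run", {}),
                  output=raw.get("output", "."))
        cfg.validate()
        return cfg

    def bias_params(self) -> dict:
        return {**self.DEFAULT_BIAS, **self.bias}

    def path_params(self) -> dict:
        return {**self.DEFAULT_PATH, **self.path}

    def run_params(self) -> dict:
        return {**self.DEFAULT_RUN, **self.run}

    def validate(self):
        b = self.bias_params()
        for key in ("temperature", "delta_t", "pace_ps", "w0_kj", "sigma_s"):
            if not b[key] > 0:
                raise ValueError(f"bias parameter {key} must be positive")
        r = self.run_params()
        for key in ("timestep_ps",):
            if not r[key] > 0:
                raise ValueError(f"run parameter {key} must be positive")
        if "n_steps" in r and r["n_steps"] < 1:
            raise ValueError("n_steps must be >= 1")
        if "seed" not in r:
            raise ValueError("a seed is mandatory for stochastic runs")

    def make_bias_template(self) -> BiasState:
        b = self.bias_params()
        walls = []
        if b.get("wall_z_threshold") is not None:
            walls.append(WallRestraint(cv_id="z", threshold=b["wall_z_threshold"],
                                       spring=b["wall_z_spring"], side="upper"))
        return BiasState(T=b["temperature"], deltaT=b["delta_t"],
                         pace=b["pace_ps"], w0=b["w0_kj"],
                         sigma=np.array([b["sigma_s"]]), walls=walls,
                         biased_cv_ids=["s"])
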