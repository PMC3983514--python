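"""Serialization: trajectory HDF5 container, CSV summaries, centerline export.

On-disk units are mm and radians throughout; every file embeds the schema
and package version.  The trajectory container is a single HDF5 file with
one group per recorded state plus the YAML config snapshot, and a
human-readable per-state CSV summary can be written alongside.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .config import SimulationConfig, config_from_dict, config_to_dict
from .growth import ContingencyTable, Trajectory
from .morphometrics import compute_metrics, out_of_sagittal_rms
from .rod import Centerline, RodState, SolveDiagnostics

SCHEMA_VERSION = 1


def _pkg_version() -> str:
    from . import __version__
    return __version__


class TrajectoryFormatError(IOError):
    pass


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Lossless trajectory container (HDF5): states, diagnostics, config, seed."""
    import yaml

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["package_version"] = _pkg_version()
        f.attrs["units"] = "mm, radians"
        f.attrs["seed"] = traj.seed
        f.attrs["truncated"] = traj.truncated
        f.attrs["truncation_reason"] = traj.truncation_reason
        f.attrs["flop_side"] = traj.flop_side or ""
        f.attrs["n_states"] = len(traj.states)
        f.create_dataset("fed_lengths", data=np.asarray(traj.fed_lengths))
        if traj.caudal_y:
            f.create_dataset("caudal_y", data=np.asarray(traj.caudal_y))
        f.create_dataset("config_yaml", data=yaml.safe_dump(
            config_to_dict(traj.config_snapshot)))
        for k, (st, diag) in enumerate(zip(traj.states, traj.solver_diagnostics)):
            g = f.create_group(f"states/{k:05d}")
            g.create_dataset("nodes", data=st.nodes)
            g.create_dataset("rest_lengths", data=st.centerline.rest_lengths)
            g.create_dataset("edge_twists", data=st.edge_twists)
            g.create_dataset("reference_frames", data=st.reference_frames)
            if st.clamp_frames is not None:
                g.create_dataset("clamp_frames", data=st.clamp_frames)
            g.attrs["fed_length"] = st.fed_length
            g.attrs["twist_total"] = st.twist_total
            g.attrs["caudal_y"] = st.caudal_y
            if diag is not None:
                g.attrs["converged"] = diag.converged
                g.attrs["iterations"] = diag.iterations
                g.attrs["grad_norm"] = diag.grad_norm
                g.attrs["energy"] = diag.energy


def read_trajectory(path: str | Path) -> Trajectory:
    import yaml

    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise TrajectoryFormatError(
                f"unsupported trajectory schema_version {version}")
        config = config_from_dict(yaml.safe_load(f["config_yaml"][()].decode()
                                                 if isinstance(f["config_yaml"][()], bytes)
                                                 else f["config_yaml"][()]))
        n = int(f.attrs["n_states"])
        if "states" not in f or len(f["states"]) != n:
            raise TrajectoryFormatError("truncated trajectory file")
        states, diags = [], []
        for k in range(n):
            g = f[f"states/{k:05d}"]
            clampf = g["clamp_frames"][()] if "clamp_frames" in g else None
            diag = None
            if "converged" in g.attrs:
                diag = SolveDiagnostics(
                    converged=bool(g.attrs["converged"]),
                    iterations=int(g.attrs["iterations"]),
                    grad_norm=float(g.attrs["grad_norm"]),
                    energy=float(g.attrs["energy"]))
            st = RodState(
                centerline=Centerline(g["nodes"][()], g["rest_lengths"][()]),
                edge_twists=g["edge_twists"][()],
                reference_frames=g["reference_frames"][()],
                fed_length=float(g.attrs["fed_length"]),
                clamp_frames=clampf,
                twist_total=float(g.attrs["twist_total"]),
                caudal_y=float(g.attrs["caudal_y"]),
                last_solve=diag)
            states.append(st)
            diags.append(diag)
        traj = Trajectory(
            states=states,
            fed_lengths=list(f["fed_lengths"][()]),
            solver_diagnostics=diags,
            config_snapshot=config,
            seed=int(f.attrs["seed"]),
            truncated=bool(f.attrs["truncated"]),
            truncation_reason=str(f.attrs["truncation_reason"]),
            flop_side=str(f.attrs["flop_side"]) or None,
            caudal_y=list(f["caudal_y"][()]) if "caudal_y" in f else [])
    return traj


def write_summary_csv(traj: Trajectory, path: str | Path) -> None:
    """Per-state morphometric summary: one row per recorded state."""
    cfg = traj.config_snapshot
    with open(path, "w", newline="") as fh:
        fh.write(f"# cardiobuckle {_pkg_version()} summary; units mm; "
                 f"schema_version {SCHEMA_VERSION}\n")
        w = csv.writer(fh)
        w.writerow(["index", "fed_length_mm", "phase", "chirality", "writhe",
                    "out_of_sagittal_rms_mm", "length_to_diameter",
                    "loop_to_cavity", "converged"])
        for k, st in enumerate(traj.states):
            m = compute_metrics(st, cfg)
            w.writerow([k, f"{st.fed_length:.3f}", m.phase.value, m.chirality.value,
                        f"{m.writhe:.6f}",
                        f"{out_of_sagittal_rms(st.nodes):.4f}",
                        f"{m.length_to_diameter:.4f}",
                        f"{m.loop_to_cavity_ratio:.4f}",
                        st.last_solve.converged if st.last_solve else ""])


def write_contingency_csv(tables: list[ContingencyTable], path: str | Path) -> None:
    """Chirality contingency table, one row per condition."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# cardiobuckle {_pkg_version()} contingency; "
                 f"schema_version {SCHEMA_VERSION}\n")
        w = csv.writer(fh)
        w.writerow(["condition", "caudal_offset_mm", "n_runs",
                    "n_d_loop", "n_l_loop", "n_indeterminate",
                    "d_percent", "l_percent"])
        for t in tables:
            w.writerow([t.condition, f"{t.caudal_offset:g}", t.n_runs,
                        t.n_d_loop, t.n_l_loop, t.n_indeterminate,
                        f"{t.d_percent:.1f}", f"{t.l_percent:.1f}"])


# ---------------------------------------------------------------------------
# centerline export

EXPORT_FORMATS = ("csv", "obj", "vtk")


def export_centerline(state, path: str | Path, fmt: str = "csv",
                      config: SimulationConfig | None = None) -> None:
    """Write the node polyline (mm, cranial to caudal) for visualization.

    ``csv``: x,y,z rows.  ``obj``: Wavefront polyline.  ``vtk``: legacy
    ASCII POLYDATA with per-node arclength, torsion sign and dome clearance
    scalars (dome clearance requires ``config``).
    """
    nodes = getattr(state, "nodes", state)
    nodes = np.asarray(nodes, dtype=float)
    path = Path(path)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(f"# cardiobuckle {_pkg_version()} centerline; units mm\n")
            w = csv.writer(fh)
            w.writerow(["x_mm", "y_mm", "z_mm"])
            for p in nodes:
                w.writerow([f"{p[0]:.9g}", f"{p[1]:.9g}", f"{p[2]:.9g}"])
    elif fmt == "obj":
        with open(path, "w") as fh:
            fh.write(f"# cardiobuckle {_pkg_version()} centerline (mm)\n")
            for p in nodes:
                fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            fh.write("l " + " ".join(str(i + 1) for i in range(len(nodes))) + "\n")
    elif fmt == "vtk":
        from .contact import dome_gap
        from .morphometrics import torsion_sign_profile
        seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        if nodes.shape[0] >= 5:
            prof = torsion_sign_profile(nodes)
            tsign = np.interp(arclen, prof[:, 0], prof[:, 1])
        else:
            tsign = np.zeros(len(nodes))
        if config is not None:
            gaps = np.array([dome_gap(p, config.cavity, config.rod.radius)
                             for p in nodes])
        else:
            gaps = np.zeros(len(nodes))
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write(f"cardiobuckle {_pkg_version()} centerline (mm)\n")
            fh.write("ASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {len(nodes)} double\n")
            for p in nodes:
                fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
            fh.write(f"LINES 1 {len(nodes) + 1}\n")
            fh.write(f"{len(nodes)} " + " ".join(map(str, range(len(nodes)))) + "\n")
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, arr in (("arclength_mm", arclen),
                              ("torsion_sign", tsign),
                              ("dome_gap_mm", gaps)):
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.12g}" for v in arr) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; use one of {EXPORT_FORMATS}")


def read_vtk_points(path: str | Path) -> np.ndarray:
    """Read back the POINTS block of a legacy ASCII VTK polyline file."""
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            j = i + 1
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in lines[j].split())
                j += 1
            return np.array(vals).reshape(n, 3)
    raise TrajectoryFormatError("no POINTS block found")
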