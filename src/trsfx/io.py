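"""File formats: PDB coordinates, structure-factor mmCIF / TSV reflections,
CCP4 mode-2 maps (P1), and CSV traces/spectra."""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd

from .icos_spectra import Spectrum
from .kinetics import TimeTrace
from .xtal_core import AtomModel, DensityMap, ReflectionSet, UnitCell

__all__ = [
    "read_pdb", "write_pdb",
    "read_sf_cif", "write_sf_cif",
    "read_hkl_tsv", "write_hkl_tsv",
    "read_ccp4", "write_ccp4",
    "read_trace_csv", "write_trace_csv",
    "read_spectrum_csv", "write_spectrum_csv",
]


# --------------------------------------------------------------------------- #
# PDB


def write_pdb(model: AtomModel, path) -> None:
    c = model.cell
    with open(path, "w") as fh:
        fh.write(f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
                 f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1           1\n")
        for i in range(len(model)):
            el = model.elements[i].upper()
            name = model.atom_names[i]
            pad = f" {name:<3s}" if len(name) < 4 else name
            record = "HETATM" if model.res_names[i] in ("HOH", "RNG") else "ATOM  "
            x, y, z = model.xyz[i]
            fh.write(f"{record}{i + 1:5d} {pad:<4s} {model.res_names[i]:<3s} A"
                     f"{model.res_ids[i]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                     f"{model.occ[i]:6.2f}{model.b[i]:6.2f}          {el:>2s}\n")
        fh.write("END\n")


def read_pdb(path) -> AtomModel:
    cell = None
    elements, res_ids, res_names, atom_names = [], [], [], []
    xyz, occ, b = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                cell = UnitCell(float(line[6:15]), float(line[15:24]),
                                float(line[24:33]), float(line[33:40]),
                                float(line[40:47]), float(line[47:54]))
            elif line.startswith(("ATOM  ", "HETATM")):
                atom_names.append(line[12:16].strip())
                res_names.append(line[17:20].strip())
                res_ids.append(int(line[22:26]))
                xyz.append([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
                occ.append(float(line[54:60]))
                b.append(float(line[60:66]))
                el = line[76:78].strip() or line[12:16].strip()[0]
                elements.append(el.capitalize())
    if cell is None:
        raise ValueError(f"{path}: no CRYST1 record")
    return AtomModel(elements=elements, res_ids=np.array(res_ids),
                     res_names=res_names, atom_names=atom_names,
                     xyz=np.array(xyz), occ=np.array(occ), b=np.array(b),
                     cell=cell)


# --------------------------------------------------------------------------- #
# reflections (structure-factor mmCIF subset, and a plain TSV)


def write_sf_cif(refl: ReflectionSet, path, block: str = "toy") -> None:
    c = refl.cell
    has_phase = refl.phase is not None
    with open(path, "w") as fh:
        fh.write(f"data_{block}\n")
        fh.write(f"_cell.length_a {c.a:.4f}\n_cell.length_b {c.b:.4f}\n"
                 f"_cell.length_c {c.c:.4f}\n_cell.angle_alpha {c.alpha:.3f}\n"
                 f"_cell.angle_beta {c.beta:.3f}\n_cell.angle_gamma {c.gamma:.3f}\n")
        fh.write("_symmetry.space_group_name_H-M 'P 1'\n")
        fh.write(f"_reflns.d_resolution_high {refl.d_min:.4f}\n")
        if np.isfinite(refl.d_max):
            fh.write(f"_reflns.d_resolution_low {refl.d_max:.4f}\n")
        fh.write(f"_trsfx.role {refl.role}\n")
        fh.write("loop_\n_refln.index_h\n_refln.index_k\n_refln.index_l\n"
                 "_refln.F_meas_au\n_refln.F_meas_sigma_au\n")
        if has_phase:
            fh.write("_refln.phase_meas\n")
        for i in range(len(refl)):
            row = (f"{refl.hkl[i, 0]} {refl.hkl[i, 1]} {refl.hkl[i, 2]} "
                   f"{refl.amp[i]:.6g} {refl.sigma[i]:.6g}")
            if has_phase:
                row += f" {refl.phase[i]:.4f}"
            fh.write(row + "\n")


def read_sf_cif(path) -> ReflectionSet:
    cell_vals = {}
    d_min, d_max, role = 0.1, np.inf, "plain"
    rows = []
    n_cols = 0
    in_loop = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("_cell."):
                key, val = line.split()
                cell_vals[key.split(".")[1]] = float(val)
            elif line.startswith("_reflns.d_resolution_high"):
                d_min = float(line.split()[1])
            elif line.startswith("_reflns.d_resolution_low"):
                d_max = float(line.split()[1])
            elif line.startswith("_trsfx.role"):
                role = line.split()[1]
            elif line == "loop_":
                in_loop = True
            elif line.startswith("_refln."):
                n_cols += 1
            elif in_loop and not line.startswith("_"):
                rows.append(line.split())
    cell = UnitCell(cell_vals["length_a"], cell_vals["length_b"],
                    cell_vals["length_c"], cell_vals.get("angle_alpha", 90),
                    cell_vals.get("angle_beta", 90),
                    cell_vals.get("angle_gamma", 90))
    arr = np.array(rows, dtype=float)
    phase = arr[:, 5] if n_cols >= 6 else None
    return ReflectionSet(hkl=arr[:, :3].astype(int), amp=arr[:, 3],
                         sigma=arr[:, 4], cell=cell, d_min=d_min, d_max=d_max,
                         phase=phase, role=role)


def write_hkl_tsv(refl: ReflectionSet, path) -> None:
    cols = {"h": refl.hkl[:, 0], "k": refl.hkl[:, 1], "l": refl.hkl[:, 2],
            "amp": refl.amp, "sigma": refl.sigma}
    if refl.phase is not None:
        cols["phase"] = refl.phase
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        c = refl.cell
        fh.write(f"# cell {c.a} {c.b} {c.c} {c.alpha} {c.beta} {c.gamma}\n"
                 f"# d_min {refl.d_min}\n# d_max {refl.d_max}\n# role {refl.role}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_hkl_tsv(path) -> ReflectionSet:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, *vals = line[1:].split()
            header[key] = vals
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    a, b, c, al, be, ga = (float(x) for x in header["cell"])
    return ReflectionSet(
        hkl=df[["h", "k", "l"]].to_numpy(int), amp=df["amp"].to_numpy(),
        sigma=df["sigma"].to_numpy(),
        cell=UnitCell(a, b, c, al, be, ga),
        d_min=float(header["d_min"][0]), d_max=float(header["d_max"][0]),
        phase=df["phase"].to_numpy() if "phase" in df else None,
        role=header.get("role", ["plain"])[0])


# --------------------------------------------------------------------------- #
# CCP4/MRC maps (mode 2, P1)


def write_ccp4(dmap: DensityMap, path) -> None:
    """Mode-2 CCP4 map, axis order X fastest (MAPC=1, MAPR=2, MAPS=3), P1."""
    nx, ny, nz = dmap.shape
    c = dmap.cell
    vals = dmap.values.astype("<f4")
    header = bytearray(1024)
    struct.pack_into("<10i", header, 0, nx, ny, nz, 2, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", header, 40, c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(vals.min()), float(vals.max()),
                     float(vals.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)          # ISPG=1 (P1), NSYMBT=0
    header[208:212] = b"MAP "
    struct.pack_into("<4B", header, 212, 0x44, 0x41, 0, 0)  # little-endian stamp
    struct.pack_into("<f", header, 216, float(vals.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.asfortranarray(vals).tobytes(order="F"))


def read_ccp4(path) -> DensityMap:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        if mode != 2:
            raise ValueError("only mode-2 (float32) maps supported")
        mapc, mapr, maps_ = struct.unpack_from("<3i", header, 64)
        if (mapc, mapr, maps_) != (1, 2, 3):
            raise ValueError("only X-fastest axis order supported")
        cella = struct.unpack_from("<6f", header, 40)
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        fh.seek(1024 + nsymbt)
        data = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4")
    vals = data.reshape((nx, ny, nz), order="F")
    return DensityMap(vals.astype(float), UnitCell(*(float(x) for x in cella)))


# --------------------------------------------------------------------------- #
# traces and spectra


def write_trace_csv(trace: TimeTrace, path) -> None:
    cols = {"time_s": trace.times, "value": trace.values}
    if trace.sigma is not None:
        cols["sigma"] = trace.sigma
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trace_csv(path) -> TimeTrace:
    df = pd.read_csv(path)
    return TimeTrace(df["time_s"].to_numpy(), df["value"].to_numpy(),
                     df["sigma"].to_numpy() if "sigma" in df else None)


def write_spectrum_csv(spec: Spectrum, path) -> None:
    with open(path, "w") as fh:
        for k, v in spec.meta.items():
            fh.write(f"# {k} {v}\n")
        pd.DataFrame({"wavelength_nm": spec.wavelengths,
                      "absorbance": spec.absorbance}).to_csv(fh, index=False)


def read_spectrum_csv(path) -> Spectrum:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, *vals = line[1:].split()
            meta[key] = " ".join(vals)
            pos = fh.tell()
        df = pd.read_csv(fh)
    return Spectrum(df["wavelength_nm"].to_numpy(),
                    df["absorbance"].to_numpy(), meta)
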