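"""Readers and writers for the formats the pipeline exchanges.

Per-ROI spectra travel as two-column CSV (mz, intensity) with ROI metadata in
a sidecar manifest TSV — the shape of flexImaging ROI exports. imzML support
is a thin wrapper over pyimzml. Images are multi-page TIFF via tifffile;
gene sets are GMT; count tables and results are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .spectra import Spectrum

_META_KEYS = ("plaque_id", "subregion", "region", "animal")


def write_roi_csv(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, index=False
    )


def read_roi_csv(path: str | Path, mode: str = "linear", meta: dict | None = None) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["mz"].to_numpy(), df["intensity"].to_numpy(), mode, meta or {})


def write_roi_dataset(spectra: list[Spectrum], outdir: str | Path) -> Path:
    """Write per-ROI CSVs plus a manifest.tsv binding files to ROI metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sp in enumerate(spectra):
        fname = f"roi_{i:04d}_{sp.mode}.csv"
        write_roi_csv(sp, outdir / fname)
        row = {"file": fname, "mode": sp.mode}
        row.update({k: sp.meta.get(k, "") for k in _META_KEYS})
        rows.append(row)
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_roi_dataset(manifest: str | Path) -> list[Spectrum]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t", dtype={"plaque_id": str})
    spectra = []
    for _, row in df.iterrows():
        meta = {k: row[k] for k in _META_KEYS if k in row}
        spectra.append(read_roi_csv(manifest.parent / row["file"], row["mode"], meta))
    return spectra


def write_imzml(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as continuous-mode imzML, one pixel per ROI spectrum."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path)) as writer:
        for i, sp in enumerate(spectra):
            writer.addSpectrum(sp.mz, sp.intensity, (i + 1, 1, 1))


def read_imzml(path: str | Path, mode: str = "linear") -> list[Spectrum]:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    out = []
    for i in range(len(parser.coordinates)):
        mz, inten = parser.getspectrum(i)
        out.append(Spectrum(np.asarray(mz), np.asarray(inten), mode, {"pixel": i}))
    return out


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting via round-trip."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
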