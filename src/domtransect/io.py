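"""Plain-text readers and writers for the transect data blocks.

All stage inputs and outputs are inspectable text at the 6-8-sample
scale of pooled transect studies: two-column CSV per 1D spectrum,
long-format CSV per COSY grid, TSV formula table and TSV metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .formulas import FormulaTable
from .nmr import Spectrum1D, SpectrumCOSY
from .synthetic import DatasetBundle

__all__ = [
    "write_spectrum_1d",
    "read_spectrum_1d",
    "write_cosy",
    "read_cosy",
    "write_bundle",
    "read_bundle",
]


def write_spectrum_1d(spectrum: Spectrum1D, path) -> None:
    pd.DataFrame({"ppm": spectrum.shifts, "intensity": spectrum.intensities}).to_csv(
        path, index=False
    )


def read_spectrum_1d(path, sample_id: str | None = None) -> Spectrum1D:
    df = pd.read_csv(path)
    return Spectrum1D(sample_id or Path(path).stem, df["ppm"].to_numpy(),
                      df["intensity"].to_numpy())


def write_cosy(cosy: SpectrumCOSY, path) -> None:
    f2, f1 = np.meshgrid(cosy.f2_shifts, cosy.f1_shifts)
    pd.DataFrame(
        {"f2_ppm": f2.ravel(), "f1_ppm": f1.ravel(),
         "intensity": cosy.intensity_grid.ravel()}
    ).to_csv(path, index=False)


def read_cosy(path, sample_id: str | None = None) -> SpectrumCOSY:
    df = pd.read_csv(path)
    f2 = np.unique(df["f2_ppm"].to_numpy())
    f1 = np.unique(df["f1_ppm"].to_numpy())
    grid = (
        df.pivot(index="f1_ppm", columns="f2_ppm", values="intensity")
        .sort_index()
        .sort_index(axis=1)
        .to_numpy()
    )
    return SpectrumCOSY(sample_id or Path(path).stem, f2, f1, grid)


def write_bundle(bundle: DatasetBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for spec in bundle.spectra_1d:
        write_spectrum_1d(spec, outdir / f"1d_{spec.sample_id}.csv")
    for cosy in bundle.spectra_cosy:
        write_cosy(cosy, outdir / f"cosy_{cosy.sample_id}.csv")
    bundle.formula_table.to_tsv(outdir / "formulas.tsv")
    meta = bundle.metadata.rename_axis("sample_id").reset_index()
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    gt = bundle.ground_truth.get("section_fractions")
    if gt is not None:
        gt.rename_axis("sample_id").to_csv(outdir / "ground_truth_sections.tsv", sep="\t")


def read_bundle(indir) -> DatasetBundle:
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t").set_index("sample_id")
    ids = list(meta.index)
    spectra_1d = [read_spectrum_1d(indir / f"1d_{sid}.csv", sid) for sid in ids]
    spectra_cosy = [read_cosy(indir / f"cosy_{sid}.csv", sid) for sid in ids]
    table = FormulaTable.from_tsv(indir / "formulas.tsv")
    ground_truth = {}
    gt_path = indir / "ground_truth_sections.tsv"
    if gt_path.exists():
        ground_truth["section_fractions"] = pd.read_csv(
            gt_path, sep="\t"
        ).set_index("sample_id")
    return DatasetBundle(spectra_1d, spectra_cosy, table, meta, ground_truth)
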