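"""End-to-end orchestration: simulate/load -> process -> integrate -> report.

The stages follow the standard integrative DOM workflow: 1D section
integration and binning, COSY SNR filtering, binning and diagonal
handling, bin-size sweep with knee selection, molecular-formula
classification, diversity summaries, Bray-Curtis/PCoA ordinations with
post-hoc vector fitting, van Krevelen Spearman maps against salinity,
and CCorA linking the NMR- and MS-based ordinations.  All defaults are
the conventional analysis constants (0.10 ppm 1D bins, 0.05 ppm COSY
bins, SNR cutoff 3, solvent regions 4.70-5.05 and 3.20-3.45 ppm,
9,999 envfit and 719 CCorA permutations, Spearman threshold p <= 0.1);
every report table carries the configuration hash and seed used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import binsize, diversity, multivariate, nmr
from .formulas import group_relative_abundances, intensity_weighted_parameter
from .synthetic import DatasetBundle, TransectScenario, generate_transect_bundle

logger = logging.getLogger("domtransect")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    bin_size_1d: float = 0.10
    bin_size_2d: float = 0.05
    solvent_regions: tuple = nmr.DEFAULT_SOLVENT_REGIONS
    snr_cutoff: float = 3.0
    window: tuple = nmr.DEFAULT_WINDOW
    strip_diagonal: bool = True
    run_sweep: bool = True
    #: sweep floor sits at the COSY digital resolution (0.02 ppm grid): finer
    #: bins than the grid are degenerate and only flatten the curve's tail
    sweep_sizes: tuple = tuple(np.round(binsize.default_size_grid(0.02, 1.0, 15), 6))
    n_permutations_envfit: int = 9999
    n_permutations_ccora: int = 719
    spearman_p_threshold: float = 0.1
    seed: int = 1

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All stage outputs of one pipeline run, as plain DataFrames."""

    section_fractions: pd.DataFrame
    compound_groups: pd.DataFrame
    sulfur_groups: pd.DataFrame
    weighted_parameters: pd.DataFrame
    diversity_table: pd.DataFrame
    sweep_table: pd.DataFrame | None
    ordination_scores: dict
    proportion_explained: dict
    vector_fits: dict
    correlation_map: pd.DataFrame
    ccora_summary: pd.DataFrame
    dissimilarity: dict
    config_hash: str
    seed: int

    def tables(self) -> dict:
        out = {
            "section_fractions": self.section_fractions,
            "compound_groups": self.compound_groups,
            "sulfur_groups": self.sulfur_groups,
            "weighted_parameters": self.weighted_parameters,
            "diversity": self.diversity_table,
            "correlation_map": self.correlation_map,
            "ccora": self.ccora_summary,
        }
        if self.sweep_table is not None:
            out["binsize_sweep"] = self.sweep_table
        for block, scores in self.ordination_scores.items():
            out[f"pcoa_scores_{block}"] = scores
        for block, fits in self.vector_fits.items():
            out[f"vector_fits_{block}"] = fits
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash={self.config_hash} seed={self.seed}\n"
        for name, frame in self.tables().items():
            path = outdir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t")


def _vector_fit_frame(fits) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "variable": f.variable,
                "dir_pc1": f.direction[0],
                "dir_pc2": f.direction[1],
                "r_squared": f.r_squared,
                "r": f.r,
                "signed_correlation": f.signed_correlation,
                "p_value": f.p_value,
                "tier": (
                    "p<0.05" if f.p_value < 0.05 else
                    "p<0.10" if f.p_value < 0.10 else
                    "p<0.15" if f.p_value < 0.15 else "ns"
                ) if np.isfinite(f.p_value) else "degenerate",
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def run_pipeline(
    config: PipelineConfig | None = None,
    bundle: DatasetBundle | None = None,
    scenario: TransectScenario | None = None,
) -> ReportBundle:
    """Run every stage on a bundle (simulated from ``scenario`` if absent)."""
    config = config or PipelineConfig()
    if bundle is None:
        scenario = scenario or TransectScenario(seed=config.seed)
        bundle = generate_transect_bundle(scenario)
        logger.info("stage=simulate samples=%d formulas=%d",
                    len(bundle.sample_ids), len(bundle.formula_table))
    ids = bundle.sample_ids

    # --- 1D NMR -----------------------------------------------------------
    processed_1d = [nmr.excise_regions(s, config.solvent_regions) for s in bundle.spectra_1d]
    section_fractions = pd.DataFrame([nmr.integrate_sections_1d(s) for s in processed_1d])
    vecs_1d = [nmr.bin_1d(s, config.bin_size_1d, config.window) for s in processed_1d]
    matrix_1d = nmr.assemble_data_matrix(vecs_1d, normalize=True)
    logger.info("stage=process-1d bins_retained=%d", matrix_1d.values.shape[1])

    # --- COSY -------------------------------------------------------------
    filtered = [nmr.snr_filter_2d(c, config.snr_cutoff) for c in bundle.spectra_cosy]
    vecs_2d = [nmr.bin_2d(c, config.bin_size_2d, config.window) for c in filtered]
    matrix_2d = nmr.assemble_data_matrix(vecs_2d, normalize=True)
    offdiag = nmr.strip_diagonal(matrix_2d)
    offdiag_norm = nmr.BinnedMatrix(
        offdiag.sample_ids,
        offdiag.values / offdiag.values.sum(axis=1, keepdims=True),
        offdiag.bin_definitions,
        normalized=True,
        diagonal_flags=offdiag.diagonal_flags,
    )
    logger.info("stage=process-2d bins_retained=%d offdiag_bins=%d",
                matrix_2d.values.shape[1], offdiag.values.shape[1])

    # --- bin-size sweep ---------------------------------------------------
    sweep_table = None
    if config.run_sweep:
        sweep = binsize.optimize_bin_size(filtered, np.asarray(config.sweep_sizes), mode="2d",
                                          window=config.window)
        sweep_table = pd.DataFrame(
            {
                "bin_size": sweep.bin_sizes,
                "n_bins": sweep.n_bins,
                "avg_bray_curtis": sweep.avg_dissimilarity,
            }
        )
        sweep_table["knee"] = False
        sweep_table.loc[sweep.knee_index, "knee"] = True
        logger.info("stage=optimize-bins knee_bin_size=%.4g r2=%.4f",
                    sweep.knee_bin_size, sweep.log_fit.r_squared)

    # --- MS classification --------------------------------------------------
    compound_groups = group_relative_abundances(bundle.formula_table, "compound")
    sulfur_groups = group_relative_abundances(bundle.formula_table, "sulfur")
    weighted = pd.DataFrame(
        {
            name: intensity_weighted_parameter(bundle.formula_table, name)
            for name in ("h_to_c", "o_to_c", "dbe", "aimod", "S")
        }
    )

    # --- diversity ----------------------------------------------------------
    ft_values = bundle.formula_table.intensities.to_numpy().T  # samples x formulas
    div_rows = []
    for i, sid in enumerate(ids):
        div_rows.append(
            {
                "sample_id": sid,
                "richness_bins": diversity.richness(matrix_2d.values[i]),
                "shannon_bins_bits": diversity.shannon_diversity(
                    matrix_2d.values[i],
                    exclude_flags=matrix_2d.diagonal_flags if config.strip_diagonal else None,
                ),
                "richness_formulas": diversity.richness(ft_values[i]),
                "shannon_formulas_bits": diversity.shannon_diversity(ft_values[i]),
            }
        )
    diversity_table = pd.DataFrame(div_rows).set_index("sample_id")

    # --- dissimilarity + ordination ----------------------------------------
    ft_rel = ft_values / ft_values.sum(axis=1, keepdims=True)
    dms = {
        "nmr": diversity.bray_curtis_matrix(matrix_2d.values, ids),
        "nmr_offdiag": diversity.bray_curtis_matrix(offdiag_norm.values, ids),
        "ms": diversity.bray_curtis_matrix(ft_rel, ids),
    }
    # ordination keeps the diagonal (its intensity carries the bulk 1D-like
    # composition); the off-diagonal matrix feeds the dissimilarity reanalysis
    ord_nmr = multivariate.pcoa(dms["nmr"])
    ord_ms = multivariate.pcoa(dms["ms"])

    covariates = bundle.metadata.join(section_fractions)
    rng = np.random.default_rng(config.seed)
    fits = {
        "nmr": _vector_fit_frame(
            multivariate.fit_environmental_vectors(
                ord_nmr, covariates, config.n_permutations_envfit,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        ),
        "ms": _vector_fit_frame(
            multivariate.fit_environmental_vectors(
                ord_ms, covariates.join(weighted), config.n_permutations_envfit,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        ),
    }

    # --- van Krevelen correlation map (vs salinity) -------------------------
    correlation_map = multivariate.spearman_correlation_map(
        bundle.formula_table,
        bundle.metadata["salinity"].to_numpy(),
        p_threshold=config.spearman_p_threshold,
    )

    # --- CCorA ---------------------------------------------------------------
    cc = multivariate.ccora(
        ord_nmr.scores.iloc[:, :2].to_numpy(),
        ord_ms.scores.iloc[:, :2].to_numpy(),
        n_permutations=config.n_permutations_ccora,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ccora_summary = pd.DataFrame(
        {
            "canonical_correlation": cc.canonical_correlations,
            "squared": cc.canonical_correlations**2,
        }
    )
    ccora_summary.attrs["pillai_trace"] = cc.pillai_trace
    ccora_summary["pillai_trace"] = cc.pillai_trace
    ccora_summary["p_value"] = cc.p_value

    return ReportBundle(
        section_fractions=section_fractions,
        compound_groups=compound_groups,
        sulfur_groups=sulfur_groups,
        weighted_parameters=weighted,
        diversity_table=diversity_table,
        sweep_table=sweep_table,
        ordination_scores={"nmr": ord_nmr.scores, "ms": ord_ms.scores},
        proportion_explained={
            "nmr": ord_nmr.proportion_explained,
            "ms": ord_ms.proportion_explained,
        },
        vector_fits=fits,
        correlation_map=correlation_map,
        ccora_summary=ccora_summary,
        dissimilarity={k: v for k, v in dms.items()},
        config_hash=config.config_hash(),
        seed=config.seed,
    )
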