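"""End-to-end driver: one config in, the full study analogue out.

Chains simulation -> panel QC -> panel build -> leave-one-out imputation
evaluation -> population-structure statistics -> coancestry clustering
-> regional screens, entirely in memory, and exposes the intermediate
objects so the CLI can serialize whichever artifacts were requested.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coancestry import cluster_coancestry, coancestry_matrix
from .containers import GenotypeMatrix, HaplotypePanel
from .eval_pipeline import (
    FrequencyBinSpec,
    aggregate_accuracy,
    diff_snp_screen,
)
from .impute_engine import HmmParams, loo_cross_validate
from .io_formats import PipelineConfig
from .panel_qc import calibrate_depth_threshold, prune_relatives, site_filter
from .popstruct import fst_matrix
from .simpop import simulate_cohort


@dataclass
class PipelineResult:
    cohort: object
    calibration: pd.DataFrame
    site_report: pd.DataFrame
    prune_removed: list[str]
    panel: HaplotypePanel
    loo_bins: pd.DataFrame
    fst: pd.DataFrame
    cluster_labels: pd.DataFrame
    diff_screen: pd.DataFrame | None


def run_all(config: PipelineConfig) -> PipelineResult:
    cohort = simulate_cohort(config.simulation, config.depth_model())

    calibration = calibrate_depth_threshold(
        cohort.ngs_calls,
        cohort.depths,
        cohort.array_calls,
        target=config.qc.concordance_target,
    )
    truth_gm = cohort.truth.genotypes()
    site_mask, site_report = site_filter(truth_gm, config.qc)
    prune = prune_relatives(truth_gm, config.qc)
    panel = cohort.truth.subset(
        sample_idx=np.array(
            [
                cohort.truth.samples["sample"].tolist().index(s)
                for s in prune.kept
            ]
        ),
        site_idx=site_mask,
    )

    typed = cohort.array_site_mask[site_mask]
    params = HmmParams.from_effective_size(
        config.hmm_effective_size,
        config.simulation.recomb_rate_per_interval,
        panel.n_haplotypes - 2,
        config.hmm_miscopy_epsilon,
    )
    dm, _ = loo_cross_validate(panel, typed, params)
    bins = FrequencyBinSpec(tuple(config.bin_edges))
    eva = aggregate_accuracy(panel.genotypes(), dm, panel.alt_freq(), bins)

    panel_gm = panel.genotypes()
    fst = fst_matrix(panel_gm)
    k_max = min(config.coancestry_k_max, panel.n_samples - 1)
    cm = coancestry_matrix(panel, params)
    assignment = cluster_coancestry(cm, k_max=k_max)
    clusters = pd.DataFrame(
        {
            "sample": panel.samples["sample"],
            "region": panel.samples["region"],
            "cluster": assignment.labels,
        }
    )

    regions = panel.samples["region"].unique()
    screen = None
    if len(regions) >= 2:
        a, b = regions[0], regions[-1]
        screen = diff_snp_screen(
            panel_gm.subset(sample_idx=(panel.samples["region"] == a).to_numpy()),
            panel_gm.subset(sample_idx=(panel.samples["region"] == b).to_numpy()),
            p_threshold=config.diff_p_threshold,
            region_a=str(a),
            region_b=str(b),
        )
    return PipelineResult(
        cohort=cohort,
        calibration=calibration,
        site_report=site_report,
        prune_removed=prune.removed,
        panel=panel,
        loo_bins=eva.per_bin,
        fst=fst,
        cluster_labels=clusters,
        diff_screen=screen,
    )


def provenance(config: PipelineConfig) -> dict:
    """Reproducibility stamp: config hash, seed and library versions.

    Deliberately excludes wall-clock time so repeated runs are
    byte-identical.
    """
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.simulation.seed,
        "versions": {
            "panelkit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }


def write_provenance(config: PipelineConfig, out_dir: Path) -> Path:
    path = Path(out_dir) / "provenance.json"
    with open(path, "w") as fh:
        json.dump(provenance(config), fh, indent=2, sort_keys=True)
    return path
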