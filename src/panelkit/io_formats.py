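"""File formats: VCF (via pysam), IMPUTE-style hap/legend/sample, YAML config.

Coordinates are 1-based inclusive on disk (VCF and legend files) and
0-based row indices in memory; the variant table keeps the 1-based
``pos`` so round-trips are lossless.  Only biallelic SNVs are accepted:
multi-allelic or non-SNV VCF records are skipped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .containers import MISSING, GenotypeMatrix, HaplotypePanel
from .errors import FormatError, InvalidConfigError
from .panel_qc import QcThresholds
from .simpop import DepthErrorModel, RegionSpec, SimulationConfig, step_error_curve

log = logging.getLogger("panelkit")

_BASES = {"A", "C", "G", "T"}


@dataclass
class VariantRecord:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str | None = None

    def validate(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position {self.pos} is not 1-based")
        if self.ref == self.alt or self.ref not in _BASES or self.alt not in _BASES:
            raise FormatError(f"bad SNV alleles {self.ref}>{self.alt}")


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(variants: pd.DataFrame, samples: list[str], fields: set[str]):
    header = pysam.VariantHeader()
    for contig in pd.unique(variants["contig"]):
        length = int(variants.loc[variants["contig"] == contig, "pos"].max()) + 1000
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    if "DP" in fields:
        header.add_line(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
        )
    if "DS" in fields:
        header.add_line(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage">'
        )
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    path: str | Path,
    gm: GenotypeMatrix,
    depths: np.ndarray | None = None,
    dosages: np.ndarray | None = None,
    phased_haplotypes: np.ndarray | None = None,
) -> Path:
    """Write genotypes (GT, optional DP and DS) as an uncompressed VCF.

    When ``phased_haplotypes`` (``(n_sites, 2 * n_samples)``) is given the
    GT field is written phased (``a|b``); otherwise unphased from the
    genotype matrix with ``./.`` for missing.  Dosages are rounded to 3
    decimals.
    """
    path = Path(path)
    samples = gm.samples["sample"].tolist()
    fields = set()
    if depths is not None:
        fields.add("DP")
    if dosages is not None:
        fields.add("DS")
    header = _vcf_header(gm.variants, samples, fields)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for m in range(gm.n_sites):
            row = gm.variants.iloc[m]
            rec = out.new_record(
                contig=str(row["contig"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
                id=str(row["id"]),
            )
            for j, s in enumerate(samples):
                sample = rec.samples[s]
                if phased_haplotypes is not None:
                    a = int(phased_haplotypes[m, 2 * j])
                    b = int(phased_haplotypes[m, 2 * j + 1])
                    sample["GT"] = (a, b)
                    sample.phased = True
                else:
                    g = int(gm.genotypes[m, j])
                    sample["GT"] = (None, None) if g == MISSING else (g - g // 2, g // 2)
                if depths is not None:
                    sample["DP"] = int(depths[m, j])
                if dosages is not None:
                    sample["DS"] = round(float(dosages[m, j]), 3)
            out.write(rec)
    return path


def read_vcf(path: str | Path) -> dict:
    """Read a biallelic-SNV VCF into a GenotypeMatrix (+DP/DS if present).

    Returns a dict with keys ``genotypes`` (GenotypeMatrix), ``depths``,
    ``dosages`` (arrays or None), ``haplotypes`` (phased matrix or None —
    present only when every call is phased), and ``n_skipped``.
    """
    variants = []
    gt_rows = []
    hap_rows = []
    dp_rows = []
    ds_rows = []
    n_skipped = 0
    all_phased = True
    has_dp = has_ds = False
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                log.warning("skipping multi-allelic record at %s:%s", rec.contig, rec.pos)
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                n_skipped += 1
                log.warning("skipping non-SNV record at %s:%s", rec.contig, rec.pos)
                continue
            variants.append(
                {
                    "id": rec.id or f"{rec.contig}:{rec.pos}",
                    "contig": rec.contig,
                    "pos": rec.pos,
                    "ref": ref,
                    "alt": alt,
                }
            )
            gts, haps, dps, dss = [], [], [], []
            for s in samples:
                call = rec.samples[s]
                alleles = call.get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    gts.append(MISSING)
                    haps.extend([MISSING, MISSING])
                    all_phased = False
                else:
                    gts.append(sum(alleles))
                    haps.extend(alleles)
                    if not call.phased:
                        all_phased = False
                dp = call.get("DP")
                if dp is not None:
                    has_dp = True
                dps.append(MISSING if dp is None else int(dp))
                ds = call.get("DS")
                if ds is not None:
                    has_ds = True
                dss.append(np.nan if ds is None else float(ds))
            gt_rows.append(gts)
            hap_rows.append(haps)
            dp_rows.append(dps)
            ds_rows.append(dss)
    if not variants:
        raise FormatError(f"{path}: no usable biallelic SNV records")
    var_df = pd.DataFrame(variants)
    sample_df = pd.DataFrame({"sample": samples, "region": "NA"})
    gm = GenotypeMatrix(np.array(gt_rows, dtype=np.int8), var_df, sample_df)
    return {
        "genotypes": gm,
        "depths": np.array(dp_rows, dtype=np.int64) if has_dp else None,
        "dosages": np.array(ds_rows, dtype=float) if has_ds else None,
        "haplotypes": np.array(hap_rows, dtype=np.int8) if all_phased else None,
        "n_skipped": n_skipped,
    }


def read_phased_vcf(
    path: str | Path, regions: pd.Series | None = None
) -> HaplotypePanel:
    """Read a fully phased VCF as a HaplotypePanel."""
    data = read_vcf(path)
    if data["haplotypes"] is None:
        raise FormatError(f"{path}: not all genotypes are phased")
    samples = data["genotypes"].samples.copy()
    if regions is not None:
        samples["region"] = samples["sample"].map(regions).fillna("NA")
    return HaplotypePanel(data["haplotypes"], data["genotypes"].variants, samples)


# ---------------------------------------------------------------------------
# hap / legend / sample


def write_hap_legend_sample(panel: HaplotypePanel, prefix: str | Path) -> dict:
    """IMPUTE-style reference panel triplet.

    ``<prefix>.hap``: space-separated 0/1, two adjacent columns per sample
    (sample k owns columns 2k and 2k+1); ``<prefix>.legend``: header then
    ``id position ref alt``; ``<prefix>.samples``: header then
    ``sample region``.
    """
    prefix = Path(prefix)
    hap_path = prefix.with_suffix(".hap")
    legend_path = prefix.with_suffix(".legend")
    sample_path = prefix.with_suffix(".samples")
    np.savetxt(hap_path, panel.haplotypes, fmt="%d", delimiter=" ")
    legend = panel.variants[["id", "pos", "ref", "alt"]].rename(
        columns={"pos": "position"}
    )
    legend.to_csv(legend_path, sep=" ", index=False)
    panel.samples[["sample", "region"]].to_csv(sample_path, sep=" ", index=False)
    return {"hap": hap_path, "legend": legend_path, "samples": sample_path}


def read_hap_legend_sample(prefix: str | Path, contig: str = "1") -> HaplotypePanel:
    prefix = Path(prefix)
    haps = np.loadtxt(prefix.with_suffix(".hap"), dtype=np.int8, ndmin=2)
    legend = pd.read_csv(prefix.with_suffix(".legend"), sep=r"\s+")
    samples = pd.read_csv(prefix.with_suffix(".samples"), sep=r"\s+")
    if len(legend) != haps.shape[0]:
        raise FormatError(
            f"legend has {len(legend)} rows but hap matrix has {haps.shape[0]}"
        )
    variants = pd.DataFrame(
        {
            "id": legend["id"],
            "contig": contig,
            "pos": legend["position"].astype(np.int64),
            "ref": legend["ref"],
            "alt": legend["alt"],
        }
    )
    return HaplotypePanel(haps, variants, samples)


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Whole-pipeline parameter block; round-trips losslessly via YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    depth_mean: float = 10.0
    depth_error_threshold: int = 8
    depth_error_low: float = 0.05
    depth_error_high: float = 0.0005
    depth_missing_below: int = 1
    qc: QcThresholds = field(default_factory=QcThresholds)
    #: scaled-recombination population size: rho = 4 * Ne * r / K.  The
    #: default matches the simulated regional sizes (hundreds), keeping
    #: rho per interval well below 1 for typical donor counts.
    hmm_effective_size: float = 100.0
    hmm_miscopy_epsilon: float = 1e-3
    bin_edges: tuple[float, ...] = (0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)
    coancestry_k_max: int = 6
    diff_p_threshold: float = 1e-7
    novel_min_ac: int = 2

    def depth_model(self) -> DepthErrorModel:
        return DepthErrorModel(
            mean_depth=self.depth_mean,
            error_curve=step_error_curve(
                self.depth_error_threshold, self.depth_error_low, self.depth_error_high
            ),
            missing_below=self.depth_missing_below,
        )

    def to_dict(self) -> dict:
        sim = asdict(self.simulation)
        sim["regions"] = [asdict(r) for r in self.simulation.regions]
        return {
            "simulation": sim,
            "depth": {
                "mean": self.depth_mean,
                "error_threshold": self.depth_error_threshold,
                "error_low": self.depth_error_low,
                "error_high": self.depth_error_high,
                "missing_below": self.depth_missing_below,
            },
            "qc": asdict(self.qc),
            "hmm": {
                "effective_size": self.hmm_effective_size,
                "miscopy_epsilon": self.hmm_miscopy_epsilon,
            },
            "bins": list(self.bin_edges),
            "coancestry": {"k_max": self.coancestry_k_max},
            "screens": {
                "diff_p_threshold": self.diff_p_threshold,
                "novel_min_ac": self.novel_min_ac,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sim = dict(data.get("simulation", {}))
        regions = [RegionSpec(**r) for r in sim.pop("regions", [])]
        sim_cfg = SimulationConfig(**sim)
        if regions:
            sim_cfg.regions = regions
        depth = data.get("depth", {})
        qc = QcThresholds(**data.get("qc", {}))
        hmm = data.get("hmm", {})
        screens = data.get("screens", {})
        return cls(
            simulation=sim_cfg,
            depth_mean=depth.get("mean", 10.0),
            depth_error_threshold=depth.get("error_threshold", 8),
            depth_error_low=depth.get("error_low", 0.05),
            depth_error_high=depth.get("error_high", 0.0005),
            depth_missing_below=depth.get("missing_below", 1),
            qc=qc,
            hmm_effective_size=data.get("hmm", {}).get("effective_size", 100.0),
            hmm_miscopy_epsilon=hmm.get("miscopy_epsilon", 1e-3),
            bin_edges=tuple(data.get("bins", cls.bin_edges)),
            coancestry_k_max=data.get("coancestry", {}).get("k_max", 6),
            diff_p_threshold=screens.get("diff_p_threshold", 1e-7),
            novel_min_ac=screens.get("novel_min_ac", 2),
        )


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidConfigError(f"{path}: not a mapping")
    return PipelineConfig.from_dict(data)
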