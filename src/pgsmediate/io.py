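"""Plain-text readers and writers for every pipeline artifact.

All tabular data travel as TSV; structured reports as JSON.  Networks are
square TSVs with ROI labels as header row and first column; ROI time series
are TSVs (rows = ROIs, columns = samples) with a JSON sidecar carrying the
sample rate and labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import BandDefinition, WeightedNetwork
from .genetics import GenotypeTable, GwasSummary

__all__ = [
    "write_network_tsv",
    "read_network_tsv",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "read_gwas_tsv",
    "write_cohort",
]

_FLOAT_FMT = "%.10g"


def write_network_tsv(net: WeightedNetwork, path) -> None:
    df = pd.DataFrame(net.w, index=net.roi_labels, columns=net.roi_labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_network_tsv(path, band: BandDefinition | None = None, session: str = "") -> WeightedNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return WeightedNetwork(
        w=df.to_numpy(dtype=float),
        roi_labels=[str(c) for c in df.columns],
        band=band,
        session=session,
    )


def write_timeseries_tsv(path, timeseries: np.ndarray, sample_rate: float, roi_labels=None) -> None:
    path = Path(path)
    labels = roi_labels or [f"roi{i}" for i in range(timeseries.shape[0])]
    pd.DataFrame(timeseries, index=labels).to_csv(
        path, sep="\t", header=False, float_format=_FLOAT_FMT
    )
    sidecar = {"sample_rate": sample_rate, "roi_labels": list(labels)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_timeseries_tsv(path) -> tuple[np.ndarray, float, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return df.to_numpy(dtype=float), float(sidecar["sample_rate"]), sidecar["roi_labels"]


def write_genotypes_tsv(genotypes: GenotypeTable, path) -> None:
    """Dosage table (rows = participants) with a two-row allele header block
    written to a sibling ``<path>.meta.tsv``."""
    path = Path(path)
    genotypes.dosage.to_csv(path, sep="\t", float_format="%g")
    genotypes.meta.to_csv(path.with_suffix(path.suffix + ".meta.tsv"), sep="\t")


def read_genotypes_tsv(path) -> GenotypeTable:
    path = Path(path)
    dosage = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    else:  # default allele labels when only dosages are supplied
        meta = pd.DataFrame(
            {"effect_allele": "A", "other_allele": "B"}, index=dosage.columns
        )
    meta.index.name = "snp"
    return GenotypeTable(dosage=dosage, meta=meta)


def read_genotypes_vcf(path) -> GenotypeTable:
    """Dosage of the ALT allele extracted from VCF GT fields."""
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires cyvcf2") from err
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, alts, refs, rows = [], [], [], []
    for variant in vcf:
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        refs.append(variant.REF)
        alts.append(variant.ALT[0] if variant.ALT else ".")
        gt = np.asarray(variant.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        dos = np.where(gt == 3, 2.0, gt)
        dos = np.where(gt == 2, np.nan, dos)
        rows.append(dos)
    dosage = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    meta = pd.DataFrame(
        {"effect_allele": alts, "other_allele": refs}, index=pd.Index(ids, name="snp")
    )
    return GenotypeTable(dosage=dosage, meta=meta)


def read_gwas_tsv(path) -> GwasSummary:
    """Summary statistics: columns snp, effect_allele (or a1), other_allele
    (or a2), beta, p; optional info."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"a1": "effect_allele", "a2": "other_allele"})
    return GwasSummary(df)


def write_cohort(cohort, outdir, write_networks: bool = True) -> Path:
    """Write a synthetic cohort to a directory of plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t", float_format=_FLOAT_FMT)
    cohort.test_scores.to_csv(out / "scores.tsv", sep="\t", float_format=_FLOAT_FMT)
    write_genotypes_tsv(cohort.genotypes, out / "genotypes.tsv")
    cohort.gwas.table.to_csv(out / "gwas.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    ids = list(cohort.covariates.index)
    if write_networks and cohort.networks is not None:
        netdir = out / "networks"
        netdir.mkdir(exist_ok=True)
        for band, arr in cohort.networks.items():
            for i, pid in enumerate(ids):
                for s_idx in range(arr.shape[1]):
                    pd.DataFrame(arr[i, s_idx]).to_csv(
                        netdir / f"{band}_ec{s_idx + 1}_{pid}.tsv",
                        sep="\t",
                        header=False,
                        index=False,
                        float_format=_FLOAT_FMT,
                    )
    truth = _jsonable(cohort.truth)
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
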