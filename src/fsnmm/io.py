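"""CSV/TSV readers and writers, genotype encoding, configuration.

The native tabular format throughout is plain CSV with headers. Feature
tables have subjects as rows (first column ``subject_id``) and ROI
labels as remaining columns; label files have columns ``subject_id``
and ``diagnosis``; genotype tables have SNP ids as columns. Subject
alignment is always by id — a file whose rows are shuffled relative to
another is realigned, never trusted positionally.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    DiagnosisLabels,
    GenotypeTable,
    ModalityMatrix,
    RoiTimeSeries,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_labels",
    "read_genotype_table",
    "write_genotype_table",
    "read_dosage_export",
    "encode_additive",
    "read_network",
    "write_network",
    "write_network_triplets",
    "read_timeseries_tsv",
    "read_config",
    "write_manifest",
    "setup_logging",
]


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def _read_csv(path, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"failed to read {what} from {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"{what} at {path} is empty")
    return df


def read_feature_table(path, modality_name: str = "") -> ModalityMatrix:
    """Subjects x ROI feature CSV -> ModalityMatrix."""
    df = _read_csv(path, "feature table")
    if df.columns[0] != "subject_id":
        raise ValueError(
            f"feature table {path}: first column must be 'subject_id', "
            f"got '{df.columns[0]}'"
        )
    ids = df["subject_id"].astype(str).tolist()
    vals = df.iloc[:, 1:]
    bad = [c for c in vals.columns if not np.issubdtype(vals[c].dtype, np.number)]
    if bad:
        raise ValueError(f"feature table {path}: non-numeric column(s) {bad}")
    return ModalityMatrix(
        modality_name=modality_name or Path(path).stem,
        values=vals.to_numpy(dtype=float),
        subject_ids=ids,
        feature_labels=[str(c) for c in vals.columns],
    )


def write_feature_table(mm: ModalityMatrix, path) -> None:
    df = pd.DataFrame(mm.values, columns=mm.feature_labels)
    df.insert(0, "subject_id", mm.subject_ids)
    df.to_csv(path, index=False)


def read_labels(path, subject_order: list[str] | None = None) -> DiagnosisLabels:
    """Label CSV (subject_id, diagnosis) -> DiagnosisLabels.

    When ``subject_order`` is given, rows are realigned to that id
    order (ids must match exactly as sets).
    """
    df = _read_csv(path, "label table")
    for col in ("subject_id", "diagnosis"):
        if col not in df.columns:
            raise ValueError(f"label table {path}: missing column '{col}'")
    df["subject_id"] = df["subject_id"].astype(str)
    if subject_order is not None:
        missing = set(subject_order) - set(df["subject_id"])
        if missing:
            raise ValueError(f"label table {path}: missing subjects {sorted(missing)}")
        df = df.set_index("subject_id").loc[list(subject_order)].reset_index()
    return DiagnosisLabels(
        labels=df["diagnosis"].to_numpy(),
        subject_ids=df["subject_id"].tolist(),
    )


def write_labels(labels: DiagnosisLabels, path) -> None:
    pd.DataFrame(
        {"subject_id": labels.subject_ids, "diagnosis": labels.labels}
    ).to_csv(path, index=False)


def read_genotype_table(path) -> GenotypeTable:
    """Genotype CSV (subject_id + one column per SNP) -> GenotypeTable.

    Cells may be raw biallelic strings ("AG") or integer codes 0/1/2;
    empty, "NA" or negative cells are flagged missing.
    """
    df = _read_csv(path, "genotype table")
    if df.columns[0] != "subject_id":
        raise ValueError(f"genotype table {path}: first column must be 'subject_id'")
    ids = df["subject_id"].astype(str).tolist()
    snps = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:].to_numpy()
    missing = np.zeros(raw.shape, dtype=bool)
    coded = True
    calls = np.empty(raw.shape, dtype=object)
    for (i, j), v in np.ndenumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() in ("", "NA", "."):
            missing[i, j] = True
            calls[i, j] = ""
            continue
        s = str(v).strip()
        try:
            f = float(s)
            if f < 0:
                missing[i, j] = True
                calls[i, j] = ""
            else:
                calls[i, j] = f
        except ValueError:
            coded = False
            calls[i, j] = s.upper()
    if coded:
        num = np.where(missing, 0.0, calls.astype(float))
        return GenotypeTable(ids, snps, num, coded=True, missing=missing)
    return GenotypeTable(ids, snps, calls, coded=False, missing=missing)


def write_genotype_table(gt: GenotypeTable, path) -> None:
    df = pd.DataFrame(gt.calls, columns=gt.snp_ids)
    df = df.mask(gt.missing, "NA")
    df.insert(0, "subject_id", gt.subject_ids)
    df.to_csv(path, index=False)


def read_dosage_export(path) -> GenotypeTable:
    """Tab-separated additive dosage export (one row per subject).

    Expected layout: a header line with ``subject_id`` followed by SNP
    ids, then one tab-separated row of 0/1/2 dosages per subject —
    e.g. a PLINK-style ``--recode A``-like text export trimmed to
    subject id + dosages.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "subject_id":
        raise ValueError(f"dosage export {path}: first column must be 'subject_id'")
    ids = df["subject_id"].astype(str).tolist()
    snps = [str(c) for c in df.columns[1:]]
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    missing = ~np.isin(vals, (0.0, 1.0, 2.0))
    vals = np.where(missing, 0.0, vals)
    return GenotypeTable(ids, snps, vals, coded=True, missing=missing)


def _encode_one(calls, missing) -> tuple[np.ndarray, np.ndarray]:
    """Additive code for one SNP column of raw biallelic strings."""
    counts: dict[str, int] = {}
    for s, miss in zip(calls, missing):
        if miss:
            continue
        s = s.replace("/", "").replace("|", "")
        if len(s) != 2:
            raise ValueError(f"malformed genotype call '{s}'")
        for a in s:
            counts[a] = counts.get(a, 0) + 1
    alleles = sorted(counts)
    if len(alleles) > 2:
        raise ValueError(f"more than two alleles observed: {alleles}")
    if not alleles:
        return np.zeros(len(calls)), np.ones(len(calls), dtype=bool)
    # major = most frequent; 50/50 ties break to the lexicographically smaller
    if len(alleles) == 1:
        major = alleles[0]
    else:
        a, b = alleles  # already lexicographically sorted
        major = a if counts[a] >= counts[b] else b
    codes = np.zeros(len(calls))
    for i, (s, miss) in enumerate(zip(calls, missing)):
        if miss:
            continue
        s = s.replace("/", "").replace("|", "")
        codes[i] = sum(1 for a in s if a != major)
    return codes, np.asarray(missing, dtype=bool)


def encode_additive(gt: GenotypeTable) -> GenotypeTable:
    """Additively encode raw biallelic calls per SNP.

    The major allele counts as 0, so homozygous-major -> 0,
    heterozygous -> 1 (order-insensitive: "AG" == "GA"),
    homozygous-minor -> 2. Missing calls stay masked; downstream users
    drop masked subjects per SNP (counts are logged).
    """
    if gt.coded:
        return gt
    n, m = len(gt.subject_ids), len(gt.snp_ids)
    codes = np.zeros((n, m))
    missing = np.zeros((n, m), dtype=bool)
    for j in range(m):
        col = gt.calls[:, j]
        vals = np.zeros(n)
        numeric = True
        for i, c in enumerate(col):
            if gt.missing[i, j]:
                continue
            try:
                vals[i] = float(c)
            except (TypeError, ValueError):
                numeric = False
                break
        if numeric and np.isin(vals[~gt.missing[:, j]], (0, 1, 2)).all():
            # column already additively coded
            codes[:, j] = vals
            missing[:, j] = gt.missing[:, j]
            continue
        codes[:, j], missing[:, j] = _encode_one(
            [str(c) for c in col], gt.missing[:, j]
        )
    n_missing = int(missing.sum())
    if n_missing:
        logger.info("encode_additive: %d missing call(s) remain masked", n_missing)
    return GenotypeTable(
        list(gt.subject_ids), list(gt.snp_ids), codes, coded=True, missing=missing
    )


def read_network(path) -> tuple[np.ndarray, list[str]]:
    """Dense N x N network CSV (subject ids as header and index)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"network {path}: header and index ids disagree")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_network(values: np.ndarray, subject_ids: list[str], path) -> None:
    pd.DataFrame(values, index=subject_ids, columns=subject_ids).to_csv(path)


def write_network_triplets(values: np.ndarray, subject_ids: list[str], path) -> None:
    """Sparse triplet TSV (i, j, weight) of the nonzero entries."""
    ii, jj = np.nonzero(values)
    pd.DataFrame(
        {
            "i": [subject_ids[a] for a in ii],
            "j": [subject_ids[b] for b in jj],
            "weight": values[ii, jj],
        }
    ).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path, subject_id: str | None = None) -> RoiTimeSeries:
    """Per-subject ROI time-series TSV: rows = timepoints, columns = ROIs."""
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        subject_id=subject_id or Path(path).stem,
        values=df.to_numpy(dtype=float),
        roi_labels=[str(c) for c in df.columns],
    )


def read_config(path) -> dict:
    """YAML run configuration -> plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_manifest(out_dir, config: dict, seed: int | None = None) -> None:
    """Record config + seed + versions beside a run's outputs."""
    import fsnmm

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "fsnmm": fsnmm.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
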