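"""Cohort I/O: a language-neutral manifest plus CSV/TSV/HDF5 payloads.

A cohort on disk is a directory with a YAML (or JSON) manifest naming its
parts::

    name: demo
    parcels: 10
    phenotypes: phenotypes.csv          # CSV, first column subject_id
    column_kinds: {age_months: continuous, sex: binary}
    units: {age_months: months}
    connectivity:
      rest: {file: rest.h5, scale: pearson_r}    # .h5 or .csv
    snps: {file: snps.tsv, encoding: dosage_012} # optional

Connectivity files are either a CSV (first column subject_id, then the
m = p(p-1)/2 edge columns in the frozen upper-triangle order) or an HDF5
file with datasets ``values`` (subjects x edges) and ``subject_ids``.
Subjects present in phenotypes but absent from a modality are kept with
all-NaN rows and flagged, never silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, ConnectivitySet, PhenotypeTable, SNPDosageMatrix
from .edges import EdgeIndex, num_edges
from .exceptions import DataError, FormatError

__all__ = [
    "load_cohort",
    "save_cohort",
    "load_timeseries",
    "dosage_from_vcf",
]


def _read_manifest(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _read_connectivity_file(
    path: Path, m: int
) -> tuple[list[str], np.ndarray]:
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            values = np.asarray(fh["values"], dtype=float)
            ids = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in fh["subject_ids"][()]
            ]
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        ids = df.iloc[:, 0].astype(str).tolist()
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[1] != m:
        raise FormatError(
            f"{path.name}: {values.shape[1] if values.ndim == 2 else '?'} edge "
            f"columns, expected {m} = p(p-1)/2"
        )
    return ids, values


def load_cohort(manifest: str | Path) -> Cohort:
    """Load an aligned :class:`~connaudit.cohort.Cohort` from a manifest file."""
    manifest = Path(manifest)
    if not manifest.exists():
        raise FormatError(f"manifest not found: {manifest}")
    cfg = _read_manifest(manifest)
    root = manifest.parent
    p = int(cfg["parcels"])
    m = num_edges(p)

    pheno_df = pd.read_csv(
        root / cfg["phenotypes"], dtype={0: str}, float_precision="round_trip"
    )
    pheno_df = pheno_df.set_index(pheno_df.columns[0])
    if pheno_df.index.has_duplicates:
        raise DataError(
            f"{cfg['phenotypes']}: duplicate subject ids "
            f"{pheno_df.index[pheno_df.index.duplicated()].unique().tolist()}"
        )
    pheno = PhenotypeTable(
        pheno_df,
        kinds=dict(cfg.get("column_kinds", {})),
        units=dict(cfg.get("units", {})),
    )
    order = pheno.subject_ids

    connectivity: dict[str, ConnectivitySet] = {}
    for task, entry in (cfg.get("connectivity") or {}).items():
        path = root / entry["file"]
        ids, values = _read_connectivity_file(path, m)
        if len(set(ids)) != len(ids):
            raise DataError(f"{path.name}: duplicate subject ids")
        frame = pd.DataFrame(values, index=ids)
        aligned = frame.reindex(order)  # NaN rows flag missing modality
        connectivity[task] = ConnectivitySet(
            task=task,
            values=aligned.to_numpy(dtype=float),
            edge_index=EdgeIndex(p),
            scale=entry.get("scale", "pearson_r"),
        )

    snps = None
    if cfg.get("snps"):
        entry = cfg["snps"]
        df = pd.read_csv(
            root / entry["file"], sep="\t", dtype={0: str},
            float_precision="round_trip",
        )
        df = df.set_index(df.columns[0]).reindex(order)
        snps = SNPDosageMatrix(
            list(df.columns),
            df.to_numpy(dtype=float),
            encoding=entry.get("encoding", "dosage_012"),
        )

    return Cohort(pheno, connectivity, snps, name=cfg.get("name", manifest.stem))


def save_cohort(
    cohort: Cohort, directory: str | Path, connectivity_format: str = "h5"
) -> Path:
    """Write a cohort as manifest + payload files; returns the manifest path.

    ``connectivity_format`` is ``'h5'`` or ``'csv'``.  Save-then-load
    round-trips values and subject order exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pheno_path = directory / "phenotypes.csv"
    cohort.phenotypes.data.to_csv(pheno_path, index_label="subject_id")

    cfg: dict = {
        "name": cohort.name,
        "parcels": next(iter(cohort.connectivity.values())).edge_index.p
        if cohort.connectivity
        else 2,
        "phenotypes": "phenotypes.csv",
        "column_kinds": dict(cohort.phenotypes.kinds),
        "units": dict(cohort.phenotypes.units),
        "connectivity": {},
    }
    ids = np.array(cohort.subject_ids)
    for task, cs in cohort.connectivity.items():
        if connectivity_format == "h5":
            fname = f"{task}.h5"
            with h5py.File(directory / fname, "w") as fh:
                fh.create_dataset("values", data=cs.values)
                fh.create_dataset(
                    "subject_ids", data=ids.astype("S")
                )
        else:
            fname = f"{task}.csv"
            frame = pd.DataFrame(cs.values, index=ids)
            frame.columns = [f"e{k}" for k in range(cs.m)]
            frame.to_csv(directory / fname, index_label="subject_id")
        cfg["connectivity"][task] = {"file": fname, "scale": cs.scale}

    if cohort.snps is not None:
        snp_path = directory / "snps.tsv"
        frame = pd.DataFrame(
            cohort.snps.values, index=ids, columns=cohort.snps.snp_ids
        )
        frame.to_csv(snp_path, sep="\t", index_label="subject_id")
        cfg["snps"] = {"file": "snps.tsv", "encoding": cohort.snps.encoding}

    manifest = directory / "manifest.yaml"
    manifest.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return manifest


def load_timeseries(path: str | Path) -> np.ndarray:
    """Read a region x time matrix from delimited text or HDF5 ('values')."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return np.asarray(fh["values"], dtype=float)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)


def dosage_from_vcf(path: str | Path, subject_ids: list[str] | None = None) -> SNPDosageMatrix:
    """Extract a dosage_012 matrix (minor-allele counts) from a VCF.

    Missing genotypes become NaN.  Requires the optional ``cyvcf2``
    dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "VCF ingestion requires the optional 'cyvcf2' dependency"
        ) from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for variant in vcf:
        # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        gt = np.asarray(variant.gt_types, dtype=float)
        dose = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, np.where(gt == 0, 0.0, np.nan)))
        rows.append(dose)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    values = np.array(rows).T if rows else np.empty((len(samples), 0))
    snps = SNPDosageMatrix(ids, values)
    if subject_ids is not None:
        frame = pd.DataFrame(values, index=samples, columns=ids)
        snps = SNPDosageMatrix(
            ids, frame.reindex(subject_ids).to_numpy(dtype=float)
        )
    return snps
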