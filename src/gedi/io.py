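"""Readers/writers: Matrix Market counts, TSV tables, GMT gene sets, and the
model archive directory.

Conventions: MTX files are 1-based per the format standard and converted to
0-based arrays at the boundary; cell order is defined by the barcodes file;
sample maps are joined by barcode string, and unmapped cells are an error,
never a silent drop.  Analysis TSVs are written at 9 significant digits;
the model archive is written at full precision so a write/read round trip
is bit-faithful for the manifest and within 1e-12 for numerics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field as _field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .model import (
    CellEmbeddings,
    CovariateBlock,
    DimensionError,
    GediError,
    GediModel,
    GenePriorBlock,
    ReferenceManifold,
    SampleTransformSet,
)

__all__ = [
    "DatasetBundle",
    "load_dataset",
    "read_counts",
    "write_counts",
    "read_dense",
    "write_dense",
    "read_sample_map",
    "read_covariates",
    "read_gene_sets",
    "save_model",
    "load_model",
    "file_sha256",
]

log = logging.getLogger("gedi")

_ANALYSIS_FMT = "%.9g"
_ARCHIVE_FMT = "%.17g"


def _read_ids(path) -> List[str]:
    ids = [line.rstrip("\n").split("\t")[0] for line in open(path)]
    ids = [x for x in ids if x]
    dup = pd.Index(ids)
    if dup.has_duplicates:
        raise GediError(f"duplicate identifiers in {path}")
    return ids


def read_counts(mtx_path, genes_path, cells_path):
    """Read an MTX count matrix with row/column sidecars.

    Returns ``(counts, gene_ids, cell_ids)`` with ``counts`` a dense
    nonnegative integer array (G, N).  Gzipped MTX is accepted.
    """
    M = scipy.io.mmread(os.fspath(mtx_path))
    if sp.issparse(M):
        M = M.toarray()
    M = np.asarray(M)
    genes = _read_ids(genes_path)
    cells = _read_ids(cells_path)
    if M.shape != (len(genes), len(cells)):
        raise DimensionError(
            f"matrix shape {M.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    if np.any(M < 0) or not np.allclose(M, np.round(M)):
        raise GediError(f"{mtx_path}: counts must be nonnegative integers")
    return M.astype(np.int64), genes, cells


def write_counts(mtx_path, counts, gene_ids, cell_ids, genes_path=None, cells_path=None):
    counts = np.asarray(counts)
    scipy.io.mmwrite(os.fspath(mtx_path), sp.coo_matrix(counts), field="integer")
    if genes_path is not None:
        Path(genes_path).write_text("".join(f"{g}\n" for g in gene_ids))
    if cells_path is not None:
        Path(cells_path).write_text("".join(f"{c}\n" for c in cell_ids))


def read_dense(path) -> Tuple[np.ndarray, List[str], List[str]]:
    """Dense matrix TSV: header row = cell ids, first column = gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise GediError(f"duplicate identifiers in {path}")
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def write_dense(path, M, row_ids, col_ids, fmt=_ANALYSIS_FMT):
    pd.DataFrame(np.asarray(M), index=row_ids, columns=col_ids).to_csv(
        path, sep="\t", float_format=fmt
    )


def read_sample_map(path, cell_ids: Sequence[str]):
    """Two-column TSV (cell, sample) joined by barcode; unmapped cells error.

    Returns ``(sample_index_per_cell, sample_ids_in_first_seen_order)``.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise GediError(f"{path}: expected two columns (cell, sample)")
    if df.iloc[0, 0] in ("cell", "barcode"):
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise GediError(
            f"{len(missing)} cells missing from sample map "
            f"(first: {missing[:3]})"
        )
    samples = list(dict.fromkeys(mapping[c] for c in cell_ids))
    index = {sid: i for i, sid in enumerate(samples)}
    return np.array([index[mapping[c]] for c in cell_ids]), samples


def read_covariates(path, sample_ids: Sequence[str]):
    """Sample-by-covariate TSV (first column = sample id) -> H (L, Q)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise GediError(f"samples missing from covariate table: {missing}")
    H = df.loc[list(sample_ids)].to_numpy(dtype=float).T
    return H, list(df.columns)


def read_gene_sets(path, gene_universe: Sequence[str], min_overlap: int = 10):
    """GMT gene sets or a weighted TSV -> prior matrix C (G, P).

    Genes outside the universe are dropped (count logged); sets overlapping
    the universe in fewer than ``min_overlap`` genes are dropped with a
    warning.  A TSV (first column = gene id, one column per set) passes its
    signed weights through unchanged.
    """
    path = Path(path)
    universe = {g: i for i, g in enumerate(gene_universe)}
    G = len(universe)
    if path.suffix.lower() == ".gmt":
        cols, names = [], []
        n_outside = 0
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, genes = parts[0], parts[2:]
            hits = [universe[g] for g in genes if g in universe]
            n_outside += sum(1 for g in genes if g and g not in universe)
            if len(hits) < min_overlap:
                log.warning(
                    "dropping gene set %s: %d genes overlap the universe "
                    "(minimum %d)",
                    name,
                    len(hits),
                    min_overlap,
                )
                continue
            col = np.zeros(G)
            col[hits] = 1.0
            cols.append(col)
            names.append(name)
        if n_outside:
            log.info("dropped %d gene-set entries outside the universe", n_outside)
        if not cols:
            raise GediError(f"no gene set in {path} overlaps the gene universe")
        return np.column_stack(cols), names
    df = pd.read_csv(path, sep="\t", index_col=0)
    hits = [g for g in df.index if g in universe]
    if not hits:
        raise GediError(f"no genes in {path} overlap the gene universe")
    keep = []
    for name in df.columns:
        nz = int((df.loc[hits, name] != 0).sum())
        if nz < min_overlap:
            log.warning(
                "dropping gene set %s: %d nonzero weights in universe "
                "(minimum %d)",
                name,
                nz,
                min_overlap,
            )
        else:
            keep.append(name)
    if not keep:
        raise GediError(f"no gene set in {path} passes the overlap threshold")
    C = np.zeros((G, len(keep)))
    rows = [universe[g] for g in hits]
    C[rows, :] = df.loc[hits, keep].to_numpy(dtype=float)
    return C, keep


@dataclass
class DatasetBundle:
    """Harmonized observations plus optional covariate/prior inputs.

    ``provenance`` records the source paths, their SHA-256 hashes and parse
    options, so a fitted model can be traced back to its exact inputs.
    """

    observations: object  # ObservationSet (imported lazily to avoid a cycle)
    H: Optional[np.ndarray] = None
    covariate_names: Optional[List[str]] = None
    C: Optional[np.ndarray] = None
    set_names: Optional[List[str]] = None
    provenance: dict = _field(default_factory=dict)


def load_dataset(
    counts_path=None,
    genes_path=None,
    cells_path=None,
    samples_path=None,
    paired_path=None,
    dense_path=None,
    covariates_path=None,
    prior_path=None,
    mode: Optional[str] = None,
    min_overlap: int = 10,
) -> DatasetBundle:
    """Read and harmonize a full dataset from files.

    The observation mode is inferred when not given (dense -> gaussian,
    paired -> binomial, else poisson).  Identifiers are harmonized across
    all components; inconsistencies raise structured errors.
    """
    from .observations import ObservationSet

    if mode is None:
        mode = "gaussian" if dense_path else ("binomial" if paired_path else "poisson")
    paths = {
        "counts": counts_path,
        "paired": paired_path,
        "dense": dense_path,
        "genes": genes_path,
        "cells": cells_path,
        "samples": samples_path,
        "covariates": covariates_path,
        "prior": prior_path,
    }
    if mode == "gaussian":
        Y, genes, cells = read_dense(dense_path)
        smap, sids = read_sample_map(samples_path, cells)
        obs = ObservationSet(
            "gaussian", smap, Y=Y, gene_ids=genes, cell_ids=cells, sample_ids=sids
        )
    else:
        M, genes, cells = read_counts(counts_path, genes_path, cells_path)
        smap, sids = read_sample_map(samples_path, cells)
        if mode == "binomial":
            M2, genes2, cells2 = read_counts(paired_path, genes_path, cells_path)
            if genes2 != genes or cells2 != cells:
                raise GediError("paired matrices have mismatched sidecars")
            obs = ObservationSet(
                "binomial", smap, M1=M, M2=M2,
                gene_ids=genes, cell_ids=cells, sample_ids=sids,
            )
        else:
            obs = ObservationSet(
                "poisson", smap, M=M, gene_ids=genes, cell_ids=cells, sample_ids=sids
            )
    bundle = DatasetBundle(observations=obs)
    if covariates_path:
        bundle.H, bundle.covariate_names = read_covariates(covariates_path, sids)
    if prior_path:
        bundle.C, bundle.set_names = read_gene_sets(
            prior_path, genes, min_overlap=min_overlap
        )
    bundle.provenance = {
        "mode": mode,
        "min_overlap": min_overlap,
        "inputs": {
            key: {"path": str(p), "sha256": file_sha256(p)}
            for key, p in paths.items()
            if p and Path(p).is_file()
        },
    }
    return bundle


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

def _ids(model: GediModel):
    genes = list(model.gene_ids) if model.gene_ids else [f"g{i}" for i in range(model.G)]
    cells = list(model.cell_ids) if model.cell_ids else [f"c{i}" for i in range(model.N)]
    samples = (
        list(model.sample_ids) if model.sample_ids else [f"s{i}" for i in range(model.Q)]
    )
    return genes, cells, samples


def save_model(model: GediModel, path) -> None:
    """Write the model as a directory of named numeric tables plus a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    genes, cells, samples = _ids(model)
    fmt = _ARCHIVE_FMT
    write_dense(path / "o_r.tsv", model.manifold.o_r[:, None], genes, ["o_r"], fmt)
    ks = [f"k{k}" for k in range(model.K)]
    write_dense(path / "Z_r.tsv", model.manifold.Z_r, genes, ks, fmt)
    write_dense(path / "delta_o.tsv", model.transforms.delta_o, genes, samples, fmt)
    (path / "delta_Z").mkdir(exist_ok=True)
    for i, sid in enumerate(samples):
        write_dense(path / "delta_Z" / f"{sid}.tsv", model.transforms.delta_Z[i], genes, ks, fmt)
    write_dense(path / "B.tsv", model.embeddings.B, ks, cells, fmt)
    write_dense(path / "s.tsv", model.embeddings.s[:, None], cells, ["s"], fmt)
    pd.DataFrame({"cell": cells, "sample": [samples[i] for i in model.sample_map]}).to_csv(
        path / "sample_map.tsv", sep="\t", index=False
    )
    if model.manifold.d is not None:
        write_dense(path / "d.tsv", model.manifold.d[:, None], ks, ["d"], fmt)
    if model.prior is not None:
        sets = (
            list(model.prior.set_names)
            if model.prior.set_names
            else [f"p{p}" for p in range(model.prior.P)]
        )
        write_dense(path / "C.tsv", model.prior.C, genes, sets, fmt)
        write_dense(path / "A.tsv", model.prior.A, sets, ks, fmt)
    if model.covariates is not None:
        covs = (
            list(model.covariates.covariate_names)
            if model.covariates.covariate_names
            else [f"h{l}" for l in range(model.covariates.L)]
        )
        write_dense(path / "H.tsv", model.covariates.H, covs, samples, fmt)
        write_dense(path / "R_o.tsv", model.covariates.R_o, genes, covs, fmt)
        (path / "R_k").mkdir(exist_ok=True)
        for k in range(model.K):
            write_dense(path / "R_k" / f"k{k}.tsv", model.covariates.R[k], genes, covs, fmt)

    manifest = {
        "format": "gedi-model-1",
        "mode": model.observation_mode,
        "G": model.G,
        "K": model.K,
        "N": model.N,
        "Q": model.Q,
        "sigma2": repr(float(model.sigma2)),
        "orthogonal_axes": model.manifold.orthogonal_axes,
        "has_prior": model.prior is not None,
        "has_covariates": model.covariates is not None,
        "has_ellipsoid": model.manifold.d is not None,
        "S_Z": repr(float(model.S_Z)),
        "S_delta_o": repr(float(model.S_delta_o)),
        "S_delta_Z": repr(float(model.S_delta_Z)),
        "fitted": bool(model.meta.get("fitted", False)),
        "sample_order": ",".join(samples),
    }
    if model.prior is not None:
        manifest["S_A"] = repr(float(model.prior.S_A))
        manifest["prior_S_Z"] = repr(float(model.prior.S_Z))
    if model.covariates is not None:
        manifest["S_Ro"] = repr(float(model.covariates.S_Ro))
        manifest["S_Rk"] = repr(float(model.covariates.S_Rk))
        manifest["cov_S_delta_o"] = repr(float(model.covariates.S_delta_o))
        manifest["cov_S_delta_Z"] = repr(float(model.covariates.S_delta_Z))
    with open(path / "manifest.tsv", "w") as fh:
        for key, val in manifest.items():
            fh.write(f"{key}\t{val}\n")


def _read_manifest(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        key, _, val = line.partition("\t")
        out[key] = val
    return out


def load_model(path) -> GediModel:
    path = Path(path)
    man = _read_manifest(path / "manifest.tsv")
    if man.get("format") != "gedi-model-1":
        raise GediError(f"{path}: not a model archive (bad or missing manifest)")
    samples = man["sample_order"].split(",")
    o_r, genes, _ = read_dense(path / "o_r.tsv")
    Z_r, _, _ = read_dense(path / "Z_r.tsv")
    delta_o, _, _ = read_dense(path / "delta_o.tsv")
    delta_Z = np.stack(
        [read_dense(path / "delta_Z" / f"{sid}.tsv")[0] for sid in samples]
    )
    B, _, cells = read_dense(path / "B.tsv")
    s, _, _ = read_dense(path / "s.tsv")
    smap_df = pd.read_csv(path / "sample_map.tsv", sep="\t", dtype=str)
    index = {sid: i for i, sid in enumerate(samples)}
    sample_map = np.array([index[x] for x in smap_df["sample"]])
    d = None
    if man.get("has_ellipsoid") == "True":
        d = read_dense(path / "d.tsv")[0][:, 0]
    prior = None
    if man.get("has_prior") == "True":
        C, _, set_names = read_dense(path / "C.tsv")
        A, _, _ = read_dense(path / "A.tsv")
        prior = GenePriorBlock(
            C=C,
            A=A,
            S_Z=float(man["prior_S_Z"]),
            S_A=float(man["S_A"]),
            set_names=set_names,
        )
    covariates = None
    if man.get("has_covariates") == "True":
        H, cov_names, _ = read_dense(path / "H.tsv")
        R_o, _, _ = read_dense(path / "R_o.tsv")
        K = Z_r.shape[1]
        R = np.stack([read_dense(path / "R_k" / f"k{k}.tsv")[0] for k in range(K)])
        covariates = CovariateBlock(
            H=H,
            R_o=R_o,
            R=R,
            S_delta_o=float(man["cov_S_delta_o"]),
            S_delta_Z=float(man["cov_S_delta_Z"]),
            S_Ro=float(man["S_Ro"]),
            S_Rk=float(man["S_Rk"]),
            covariate_names=cov_names,
        )
    model = GediModel(
        manifold=ReferenceManifold(
            o_r[:, 0], Z_r, man.get("orthogonal_axes") == "True", d
        ),
        transforms=SampleTransformSet(delta_o, delta_Z),
        embeddings=CellEmbeddings(B, s[:, 0]),
        sigma2=float(man["sigma2"]),
        sample_map=sample_map,
        observation_mode=man["mode"],
        prior=prior,
        covariates=covariates,
        gene_ids=genes,
        cell_ids=cells,
        sample_ids=samples,
        S_Z=float(man["S_Z"]),
        S_delta_o=float(man["S_delta_o"]),
        S_delta_Z=float(man["S_delta_Z"]),
    )
    model.meta["fitted"] = man.get("fitted") == "True"
    return model


def write_run_manifest(path, config: dict, inputs: Sequence[str], seed) -> None:
    """JSON record of a CLI run: config, seed, versions, input hashes."""
    import scipy as _scipy

    canonical = json.dumps(
        {k: str(v) for k, v in config.items()}, sort_keys=True
    ).encode()
    record = {
        "config": config,
        "config_hash": hashlib.sha256(canonical).hexdigest(),
        "seed": seed,
        "versions": {
            "gedi": "0.1.0",
            "numpy": np.__version__,
            "scipy": _scipy.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {str(p): file_sha256(p) for p in inputs if p and Path(p).is_file()},
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
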