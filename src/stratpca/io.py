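"""File formats and run plumbing: EIGENSTRAT text genotypes, TSV matrices,
flat key:value parameter/run configs, result writers, and manifests.

Only transparent text formats are supported (geno/snp/ind, TSV); packed or
binary variants, PLINK and VCF are deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import GenotypeMatrix, ParamEstimates
from .model import CovParams, ModelError, PopulationLayout
from .reduced import ReducedEigenSolution

__all__ = [
    "ParseError",
    "RunConfig",
    "read_geno",
    "write_geno",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_params_config",
    "write_params_config",
    "read_run_config",
    "write_run_config",
    "write_eigen_tsv",
    "write_estimates_tsv",
    "write_assoc_tsv",
    "write_report_tsv",
    "write_manifest",
]

logger = logging.getLogger(__name__)

MISSING_TSV = "."


class ParseError(ValueError):
    """Raised on malformed input files, with line information."""


@dataclass
class RunConfig:
    """Flat run configuration; round-trips losslessly through key:value text."""

    seed: int = 0
    alpha: float = 0.01
    relative_risk: float = 1.5
    snps_per_category: int = 10_000
    fst_list: tuple[float, ...] = (0.01, 0.003)
    labels: tuple[str, ...] = ("P1", "P2", "P3")
    sizes: tuple[int, ...] = (110, 140, 230)
    num_pcs: int = 2
    method: str = "popu"
    out_dir: str = "."


def read_geno(geno_path, snp_path, ind_path) -> GenotypeMatrix:
    """Read EIGENSTRAT text genotypes (one SNP per line, one char per sample).

    Characters 0/1/2 are variant-allele counts, 9 is missing.  Individual
    ids and population labels come from columns 1 and 3 of the ind file,
    marker ids from column 1 of the snp file.
    """
    ind_lines = _read_nonempty(ind_path)
    individual_ids, labels = [], []
    for ln, line in ind_lines:
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"{ind_path}:{ln}: expected 'id gender label'")
        individual_ids.append(parts[0])
        labels.append(parts[2])
    marker_ids = []
    for ln, line in _read_nonempty(snp_path):
        parts = line.split()
        if not parts:
            raise ParseError(f"{snp_path}:{ln}: empty SNP record")
        marker_ids.append(parts[0])
    n = len(individual_ids)
    rows = []
    geno_lines = _read_nonempty(geno_path)
    for ln, line in geno_lines:
        if len(line) != n:
            raise ParseError(
                f"{geno_path}:{ln}: row has {len(line)} genotypes but the ind "
                f"file lists {n} individuals"
            )
        if not set(line) <= {"0", "1", "2", "9"}:
            bad = sorted(set(line) - {"0", "1", "2", "9"})
            raise ParseError(f"{geno_path}:{ln}: invalid characters {bad}")
        row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
        rows.append(row)
    if len(rows) != len(marker_ids):
        raise ParseError(
            f"{geno_path}: {len(rows)} genotype rows but {len(marker_ids)} SNP "
            f"records in {snp_path}"
        )
    values = np.asarray(rows, dtype=float)
    values[values == 9] = np.nan
    logger.info("read_geno: %d markers x %d individuals", len(rows), n)
    return GenotypeMatrix(values, tuple(marker_ids), tuple(individual_ids),
                          tuple(labels))


def write_geno(G: GenotypeMatrix, geno_path, snp_path, ind_path) -> None:
    """Write EIGENSTRAT text genotype, snp and ind files."""
    codes = np.where(np.isnan(G.values), 9, G.values).astype(int)
    with open(geno_path, "w") as fh:
        for row in codes:
            fh.write("".join(map(str, row)) + "\n")
    with open(snp_path, "w") as fh:
        for i, mid in enumerate(G.marker_ids):
            fh.write(f"{mid}\t1\t0.0\t{i + 1}\n")
    with open(ind_path, "w") as fh:
        for iid, lab in zip(G.individual_ids, G.labels):
            fh.write(f"{iid}\tU\t{lab}\n")


def read_genotype_tsv(matrix_path, labels_path) -> GenotypeMatrix:
    """Read a markers x individuals TSV ('.' = missing) plus a label sidecar."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    values = df.replace(MISSING_TSV, np.nan).to_numpy(dtype=float)
    lab_df = pd.read_csv(labels_path, sep="\t", header=None,
                         names=["id", "label"], dtype=str)
    lab_map = dict(zip(lab_df["id"], lab_df["label"]))
    missing = [c for c in df.columns if c not in lab_map]
    if missing:
        raise ParseError(f"{labels_path}: no label for individuals {missing}")
    labels = tuple(lab_map[c] for c in df.columns)
    return GenotypeMatrix(values, tuple(df.index.astype(str)),
                          tuple(df.columns.astype(str)), labels)


def write_genotype_tsv(G: GenotypeMatrix, matrix_path, labels_path) -> None:
    df = pd.DataFrame(G.values, index=list(G.marker_ids),
                      columns=list(G.individual_ids))
    out = df.map(lambda v: MISSING_TSV if np.isnan(v) else str(int(v)))
    out.index.name = "marker"
    out.to_csv(matrix_path, sep="\t")
    with open(labels_path, "w") as fh:
        for iid, lab in zip(G.individual_ids, G.labels):
            fh.write(f"{iid}\t{lab}\n")


def _read_nonempty(path) -> list[tuple[int, str]]:
    with open(path) as fh:
        return [
            (i + 1, line.rstrip("\n"))
            for i, line in enumerate(fh)
            if line.strip()
        ]


def _parse_kv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln, line in _read_nonempty(path):
        if line.lstrip().startswith("#"):
            continue
        if ":" not in line:
            raise ParseError(f"{path}:{ln}: expected 'key: value'")
        key, value = line.split(":", 1)
        out[key.strip()] = value.strip()
    return out


def read_params_config(path) -> tuple[PopulationLayout, CovParams]:
    """Read layout and covariance parameters from flat key:value text.

    Expected keys: ``labels``, ``sizes``, ``sigma2``, ``c`` (whitespace
    separated, one entry per population) and ``d_<lab1>_<lab2>`` for every
    unordered pair of distinct populations.
    """
    kv = _parse_kv(path)
    for key in ("labels", "sizes", "sigma2", "c"):
        if key not in kv:
            raise ParseError(f"{path}: missing required key {key!r}")
    labels = tuple(kv["labels"].split())
    sizes = tuple(int(x) for x in kv["sizes"].split())
    layout = PopulationLayout(labels, sizes)
    sigma2 = np.array([float(x) for x in kv["sigma2"].split()])
    c = np.array([float(x) for x in kv["c"].split()])
    K = layout.K
    if sigma2.shape != (K,) or c.shape != (K,):
        raise ParseError(f"{path}: sigma2/c must list {K} values")
    d = np.zeros((K, K))
    for s in range(K):
        for t in range(s + 1, K):
            key = f"d_{labels[s]}_{labels[t]}"
            alt = f"d_{labels[t]}_{labels[s]}"
            if key in kv:
                d[s, t] = d[t, s] = float(kv[key])
            elif alt in kv:
                d[s, t] = d[t, s] = float(kv[alt])
            elif K > 1:
                raise ParseError(f"{path}: missing key {key!r}")
    return layout, CovParams(sigma2=sigma2, c=c, d=d, adjusted=False)


def write_params_config(path, layout: PopulationLayout, params: CovParams) -> None:
    if params.K != layout.K:
        raise ModelError("layout and parameters disagree on K")
    lines = [
        "labels: " + " ".join(layout.labels),
        "sizes: " + " ".join(str(s) for s in layout.sizes),
        "sigma2: " + " ".join(repr(float(x)) for x in params.sigma2),
        "c: " + " ".join(repr(float(x)) for x in params.c),
    ]
    for s in range(layout.K):
        for t in range(s + 1, layout.K):
            lines.append(
                f"d_{layout.labels[s]}_{layout.labels[t]}: "
                f"{float(params.d[s, t])!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


_TUPLE_FIELDS = {"fst_list": float, "labels": str, "sizes": int}


def read_run_config(path) -> RunConfig:
    kv = _parse_kv(path)
    kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in kv:
            continue
        raw = kv[f.name]
        if f.name in _TUPLE_FIELDS:
            kwargs[f.name] = tuple(_TUPLE_FIELDS[f.name](x) for x in raw.split())
        elif f.type == "int":
            kwargs[f.name] = int(raw)
        elif f.type == "float":
            kwargs[f.name] = float(raw)
        else:
            kwargs[f.name] = raw
    return RunConfig(**kwargs)


def write_run_config(path, cfg: RunConfig) -> None:
    lines = []
    for f in dataclasses.fields(RunConfig):
        value = getattr(cfg, f.name)
        if isinstance(value, tuple):
            value = " ".join(str(v) for v in value)
        lines.append(f"{f.name}: {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_eigen_tsv(sol: ReducedEigenSolution, eigenvalues_path, axes_path) -> None:
    """Write eigenvalues and per-population axis coordinates as TSV.

    Axes TSV: rows = populations, columns = axes (``axis1`` = largest
    eigenvalue, trivial axis included and flagged in the eigenvalue file).
    """
    ev = pd.DataFrame(
        {
            "axis": [f"axis{j + 1}" for j in range(sol.K)],
            "eigenvalue": sol.eigenvalues,
            "trivial": [int(j == sol.trivial_index) for j in range(sol.K)],
        }
    )
    ev.to_csv(eigenvalues_path, sep="\t", index=False)
    axes = pd.DataFrame(
        sol.coefficients.T,
        index=list(sol.layout.labels),
        columns=[f"axis{j + 1}" for j in range(sol.K)],
    )
    axes.index.name = "population"
    axes.to_csv(axes_path, sep="\t")


def write_estimates_tsv(est: ParamEstimates, path) -> None:
    """Parameter estimates with SEs: one row per (kind, populations) entry."""
    rows = []
    labels = est.layout.labels
    for s, lab in enumerate(labels):
        rows.append(("sigma2", lab, lab, est.params.sigma2[s], est.se_sigma2[s],
                     est.cells_sigma2[s]))
    for s, lab in enumerate(labels):
        rows.append(("c", lab, lab, est.params.c[s], est.se_c[s], est.cells_c[s]))
    for s in range(len(labels)):
        for t in range(s + 1, len(labels)):
            rows.append(("d", labels[s], labels[t], est.params.d[s, t],
                         est.se_d[s, t], est.cells_d[s, t]))
    pd.DataFrame(
        rows, columns=["kind", "pop1", "pop2", "estimate", "se", "cells"]
    ).to_csv(path, sep="\t", index=False)


def write_assoc_tsv(path, marker_ids, chi2, p, direction, testable, method) -> None:
    pd.DataFrame(
        {
            "marker": list(marker_ids),
            "chi2": chi2,
            "p": p,
            "direction": direction,
            "testable": np.asarray(testable).astype(int),
            "method": method,
        }
    ).to_csv(path, sep="\t", index=False)


def write_report_tsv(report, path) -> None:
    """SimulationReport table: rows category x null/causal, columns methods."""
    out = report.table.copy()
    out.index.name = "category"
    out.to_csv(path, sep="\t", float_format="%.4f")


def write_manifest(path, config: dict) -> None:
    """Record the exact run parameters, a config hash and package version."""
    from . import __version__

    payload = dict(config)
    payload["stratpca_version"] = __version__
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
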