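"""Readers and writers for genotype, phenotype and marker-ranking tables.

Genotype tables are plain text (tab- or comma-separated): a header row
of marker identifiers, one row per individual with its identifier in
the first column and strictly 0/1 genotype calls.  Phenotype tables
have the same layout with trait names in the header and real values
(``NA`` or empty = missing).  Marker identifiers of the form
``chr:pos`` (1-based position) unlock BED output (0-based, half-open)
for genome-browser display.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RVMModel
from .ensemble import MarkerRanking
from .kernels import KernelSpec

__all__ = [
    "GenotypeTable",
    "PhenotypeTable",
    "read_genotypes",
    "read_phenotypes",
    "write_genotypes",
    "write_phenotypes",
    "align_and_filter",
    "write_ranking",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_CHRPOS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+)$")


def _parse_chrpos(marker_id: str) -> tuple[str, int] | None:
    m = _CHRPOS_RE.match(marker_id)
    if m is None:
        return None
    return m.group("chrom"), int(m.group("pos"))


@dataclass
class GenotypeTable:
    """N individuals x M biallelic markers, coded strictly 0/1."""

    individual_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual IDs in genotype table")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker IDs in genotype table")
        n, m = self.values.shape
        if n != len(self.individual_ids) or m != len(self.marker_ids):
            raise ValueError("genotype matrix shape does not match ID lists")
        parsed = [_parse_chrpos(mid) is not None for mid in self.marker_ids]
        if any(parsed) and not all(parsed):
            bad = self.marker_ids[parsed.index(False)]
            raise ValueError(
                f"marker IDs mix chr:pos and plain formats (first offender: {bad!r})"
            )
        self.has_positions = all(parsed) and len(parsed) > 0

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def positions(self) -> list[tuple[str, int]]:
        if not self.has_positions:
            raise ValueError("marker IDs are not chr:pos formatted")
        return [_parse_chrpos(mid) for mid in self.marker_ids]


@dataclass
class PhenotypeTable:
    """N individuals x T traits, real-valued with NaN for missing readings."""

    individual_ids: list[str]
    trait_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual IDs in phenotype table")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ValueError("duplicate trait names in phenotype table")
        n, t = self.values.shape
        if n != len(self.individual_ids) or t != len(self.trait_names):
            raise ValueError("phenotype matrix shape does not match ID lists")

    def trait(self, name: str) -> np.ndarray:
        if name not in self.trait_names:
            raise KeyError(f"unknown trait {name!r}; available: {self.trait_names}")
        return self.values[:, self.trait_names.index(name)]


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "," if str(path).endswith(".csv") else "\t"


def read_genotypes(path, dialect: str | None = None) -> GenotypeTable:
    """Read and validate a genotype table; non-0/1 cells are reported by coordinate."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    values = df.to_numpy(dtype=float)
    bad = ~np.isin(values, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary genotype value {df.iat[i, j]!r} for individual "
            f"{df.index[i]!r} at marker {df.columns[j]!r} in {path}"
        )
    return GenotypeTable(
        individual_ids=[str(x) for x in df.index],
        marker_ids=[str(c) for c in df.columns],
        values=values,
    )


def write_genotypes(g: GenotypeTable, path, dialect: str | None = None) -> None:
    df = pd.DataFrame(g.values.astype(int), index=g.individual_ids, columns=g.marker_ids)
    df.index.name = "individual"
    df.to_csv(path, sep=_sep_for(path, dialect))


def read_phenotypes(path, dialect: str | None = None) -> PhenotypeTable:
    """Read a phenotype table; ``NA`` and empty cells become NaN (missing)."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0, na_values=["NA", ""])
    table = PhenotypeTable(
        individual_ids=[str(x) for x in df.index],
        trait_names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )
    for name in table.trait_names:
        n_missing = int(np.isnan(table.trait(name)).sum())
        if n_missing:
            logger.info("trait %s: %d missing readings", name, n_missing)
    return table


def write_phenotypes(p: PhenotypeTable, path, dialect: str | None = None) -> None:
    df = pd.DataFrame(p.values, index=p.individual_ids, columns=p.trait_names)
    df.index.name = "individual"
    df.to_csv(path, sep=_sep_for(path, dialect), na_rep="NA")


def align_and_filter(
    g: GenotypeTable, p: PhenotypeTable, trait: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Match individuals by ID and drop those with a missing trait value.

    Returns the genotype matrix, the target vector and the kept IDs in
    genotype-file order.
    """
    pheno_index = {iid: i for i, iid in enumerate(p.individual_ids)}
    trait_values = p.trait(trait)
    rows, targets, kept = [], [], []
    for i, iid in enumerate(g.individual_ids):
        j = pheno_index.get(iid)
        if j is None:
            continue
        v = trait_values[j]
        if np.isnan(v):
            continue
        rows.append(i)
        targets.append(v)
        kept.append(iid)
    if len(kept) == 0 and not (set(g.individual_ids) & set(p.individual_ids)):
        raise ValueError("genotype and phenotype tables share no individual IDs")
    if len(kept) < 2:
        raise ValueError(
            f"only {len(kept)} usable individuals for trait {trait!r} after filtering"
        )
    return g.values[rows], np.asarray(targets, dtype=float), kept


def write_ranking(
    r: MarkerRanking, g: GenotypeTable, path, format: str = "tsv", threshold: float | None = None
) -> None:
    """Write ranked markers as TSV or BED.

    TSV columns: marker_id, chrom, pos, count, rank_fraction,
    mean_weight, sign, rank_order (chrom/pos empty for non-positional
    IDs).  BED rows are ``chrom, pos-1, pos, marker_id, score`` with
    score = round(1000 * rank_fraction) — 0-based half-open, one line
    per ranked marker.
    """
    if r.n_markers != g.n_markers:
        raise ValueError("ranking and genotype table disagree on marker count")
    frame = r.to_frame()
    if threshold is not None:
        frame = frame[frame["rank_fraction"] >= threshold]
    if format == "tsv":
        out = pd.DataFrame(
            {
                "marker_id": [g.marker_ids[m] for m in frame["marker"]],
                "chrom": "",
                "pos": "",
                "count": frame["count"].to_numpy(),
                "rank_fraction": [f"{x:.6g}" for x in frame["rank_fraction"]],
                "mean_weight": [f"{x:.10g}" for x in frame["mean_weight"]],
                "sign": frame["sign"].to_numpy(),
                "rank_order": np.arange(1, len(frame) + 1),
            }
        )
        if g.has_positions:
            pos = g.positions()
            out["chrom"] = [pos[m][0] for m in frame["marker"]]
            out["pos"] = [pos[m][1] for m in frame["marker"]]
        out.to_csv(path, sep="\t", index=False)
    elif format == "bed":
        if not g.has_positions:
            raise ValueError("BED output requires chr:pos marker IDs")
        pos = g.positions()
        with open(path, "w") as fh:
            for m, frac in zip(frame["marker"], frame["rank_fraction"]):
                chrom, p1 = pos[m]
                fh.write(
                    f"{chrom}\t{p1 - 1}\t{p1}\t{g.marker_ids[m]}\t{round(1000 * frac)}\n"
                )
    else:
        raise ValueError(f"unknown ranking format {format!r} (expected 'tsv' or 'bed')")


def save_model(model: RVMModel, path) -> None:
    """Serialise a fitted model to a self-describing JSON archive.

    Kernel models keep only the genotype rows of their relevance
    vectors, not the full training set.
    """
    payload = {
        "format": "rvmgs-model",
        "version": 1,
        "basis_kind": model.basis_kind,
        "n_features": model.n_features,
        "relevance_indices": model.relevance_indices.tolist(),
        "relevance_weights": model.relevance_weights.tolist(),
        "sigma2": model.sigma2,
        "target_mean": model.target_mean,
        "target_scale": model.target_scale,
        "n_iterations": model.n_iterations,
        "log_ml": model.log_ml if np.isfinite(model.log_ml) else None,
        "kernel": None,
        "rv_inputs": None,
    }
    if model.kernel is not None:
        payload["kernel"] = {
            "family": model.kernel.family,
            "gamma": model.kernel.gamma,
            "c": model.kernel.c,
            "d": model.kernel.d,
        }
    if model.rv_inputs is not None:
        payload["rv_inputs"] = model.rv_inputs.astype(int).tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> RVMModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "rvmgs-model":
        raise ValueError(f"{path} is not an rvmgs model archive")
    kernel = None
    if payload["kernel"] is not None:
        k = payload["kernel"]
        kernel = KernelSpec(family=k["family"], gamma=k["gamma"], c=k["c"], d=k["d"])
    rv_inputs = None
    if payload["rv_inputs"] is not None:
        rv_inputs = np.asarray(payload["rv_inputs"], dtype=float)
    return RVMModel(
        basis_kind=payload["basis_kind"],
        relevance_indices=np.asarray(payload["relevance_indices"], dtype=int),
        relevance_weights=np.asarray(payload["relevance_weights"], dtype=float),
        sigma2=payload["sigma2"],
        n_features=payload["n_features"],
        kernel=kernel,
        rv_inputs=rv_inputs,
        target_mean=payload["target_mean"],
        target_scale=payload["target_scale"],
        n_iterations=payload["n_iterations"],
        log_ml=payload["log_ml"] if payload["log_ml"] is not None else float("nan"),
    )
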