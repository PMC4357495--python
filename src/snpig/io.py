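"""Readers and writers for the formats the toolkit touches.

Genotypes travel either as a simple tab-delimited matrix (header of SNP
ids plus a final ``phenotype`` column, one row per sample) or as PLINK
PED/MAP text files with alleles recoded to per-SNP minor-allele counts.
Gene intervals come from BED (0-based half-open on disk, converted to
1-based inclusive in memory).  All writers emit a comment header with the
tool version, seed and a configuration hash; readers skip ``#`` lines.

Missing genotypes use the sentinel -1; contingency counting drops
individuals missing at either SNP of a pair (pairwise deletion).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .scan import SnpAnnotation

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_plink_ped_map",
    "write_plink_ped_map",
    "read_bed_intervals",
    "write_records",
    "read_records",
    "write_network",
    "write_centrality",
    "write_modules",
    "write_power_table",
]

MISSING = -1


class FormatError(ValueError):
    """Malformed input file; inputs are rejected, never silently coerced."""


@dataclass
class GenotypeDataset:
    """In-memory case/control genotype dataset.

    ``matrix`` holds minor-allele counts {0, 1, 2} (``MISSING`` = -1) with
    one row per sample; ``phenotype`` is 0 for case, 1 for control.
    """

    snp_ids: list[str]
    sample_ids: list[str]
    matrix: np.ndarray
    phenotype: np.ndarray
    annotations: list[SnpAnnotation] | None = field(default=None)

    def __post_init__(self) -> None:
        n, m = self.matrix.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("matrix dimensions do not match id lists")
        if len(self.phenotype) != n:
            raise ValueError("phenotype must be present for every sample")
        if self.annotations is not None and len(self.annotations) != m:
            raise ValueError("annotations must match SNP count")


def _config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(seed: int | None, config: dict | None) -> str:
    return (
        f"# snpig {__version__}\n"
        f"# seed: {'none' if seed is None else seed}\n"
        f"# config: {_config_hash(config)}\n"
    )


def read_genotype_tsv(path) -> GenotypeDataset:
    """Read the tab-delimited genotype matrix format.

    Header row: SNP ids then ``phenotype``; each following row is one
    sample.  Cells must be 0, 1, 2, or -1 (missing); the phenotype column
    must be 0 (case) or 1 (control).  Malformed cells are rejected with
    their row/column coordinates.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[-1] != "phenotype":
        raise FormatError(f"{path}: last header column must be 'phenotype'")
    snp_ids = header[:-1]
    if len(set(snp_ids)) != len(snp_ids):
        raise FormatError(f"{path}: duplicate SNP ids")
    rows = []
    pheno = []
    for r, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}: row {r} has {len(cells)} columns, expected {len(header)}")
        for c, cell in enumerate(cells, start=1):
            if cell not in {"0", "1", "2", "-1"}:
                raise FormatError(f"{path}: invalid value {cell!r} at row {r}, column {c}")
        *geno, ph = cells
        if ph not in {"0", "1"}:
            raise FormatError(f"{path}: invalid phenotype {ph!r} at row {r}")
        rows.append([int(g) for g in geno])
        pheno.append(int(ph))
    return GenotypeDataset(
        snp_ids=snp_ids,
        sample_ids=[f"s{i + 1}" for i in range(len(rows))],
        matrix=np.asarray(rows, dtype=np.int8),
        phenotype=np.asarray(pheno, dtype=np.int8),
    )


def write_genotype_tsv(
    dataset: GenotypeDataset, path, seed: int | None = None, config: dict | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_lines(seed, config))
        fh.write("\t".join([*dataset.snp_ids, "phenotype"]) + "\n")
        for row, ph in zip(dataset.matrix, dataset.phenotype):
            fh.write("\t".join(str(int(v)) for v in row) + f"\t{int(ph)}\n")


def _minor_allele(allele_counts: dict[str, int]) -> str:
    """The rarer of the two alleles; ties broken alphabetically."""
    return min(allele_counts, key=lambda a: (allele_counts[a], a))


def read_plink_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Read PLINK PED/MAP, recoding alleles to minor-allele counts.

    The minor allele of each SNP is determined from the data (the rarer
    allele; alphabetical on ties).  PED phenotype 2 maps to case (0) and 1
    to control (1).  ``0`` alleles are missing; more than two observed
    alleles at a SNP is a format error.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_rows = [
        ln.split() for ln in map_path.read_text().splitlines() if ln and not ln.startswith("#")
    ]
    for row in map_rows:
        if len(row) != 4:
            raise FormatError(f"{map_path}: expected 4 columns, got {len(row)}")
    snp_ids = [row[1] for row in map_rows]
    annotations = [
        SnpAnnotation(snp_id=row[1], chromosome=row[0], position=int(row[3]))
        for row in map_rows
    ]
    m = len(snp_ids)

    sample_ids = []
    pheno = []
    allele_rows = []
    for ln in ped_path.read_text().splitlines():
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f"{ped_path}: sample {parts[1] if len(parts) > 1 else '?'} has "
                f"{len(parts) - 6} allele columns, expected {2 * m}"
            )
        sample_ids.append(parts[1])
        if parts[5] == "2":
            pheno.append(0)  # case
        elif parts[5] == "1":
            pheno.append(1)  # control
        else:
            raise FormatError(f"{ped_path}: phenotype must be 1/2, got {parts[5]!r}")
        allele_rows.append(parts[6:])

    alleles = np.asarray(allele_rows, dtype=object).reshape(len(sample_ids), m, 2)
    matrix = np.empty((len(sample_ids), m), dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        observed = {}
        for a in col.ravel():
            if a != "0":
                observed[a] = observed.get(a, 0) + 1
        if len(observed) > 2:
            raise FormatError(f"{ped_path}: SNP {snp_ids[j]} has {len(observed)} alleles")
        if not observed:
            matrix[:, j] = MISSING
            continue
        minor = _minor_allele(observed)
        missing = (col == "0").any(axis=1)
        counts = (col == minor).sum(axis=1)
        matrix[:, j] = np.where(missing, MISSING, counts)
    return GenotypeDataset(
        snp_ids=snp_ids,
        sample_ids=sample_ids,
        matrix=matrix,
        phenotype=np.asarray(pheno, dtype=np.int8),
        annotations=annotations,
    )


def write_plink_ped_map(
    dataset: GenotypeDataset, ped_path, map_path, minor: str = "A", major: str = "B"
) -> None:
    """Write PED/MAP with letters ``minor``/``major`` encoding the counts."""
    anns = dataset.annotations or [
        SnpAnnotation(s, "0", j + 1) for j, s in enumerate(dataset.snp_ids)
    ]
    with Path(map_path).open("w") as fh:
        for a in anns:
            fh.write(f"{a.chromosome}\t{a.snp_id}\t0\t{a.position}\n")
    code = {2: f"{minor} {minor}", 1: f"{minor} {major}", 0: f"{major} {major}", MISSING: "0 0"}
    with Path(ped_path).open("w") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            ped_pheno = 2 if dataset.phenotype[i] == 0 else 1
            cells = " ".join(code[int(g)] for g in dataset.matrix[i])
            fh.write(f"F{i + 1} {sid} 0 0 0 {ped_pheno} {cells}\n")


def read_bed_intervals(path) -> list[tuple[str, int, int, str]]:
    """Gene intervals from 4+ column BED, as 1-based inclusive tuples.

    BED is 0-based half-open: a line ``chr22 99 200 GENE1`` becomes
    ``("chr22", 100, 200, "GENE1")``.
    """
    out = []
    for ln in Path(path).read_text().splitlines():
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}: BED needs >= 4 columns, got {len(parts)}")
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        if start >= end:
            raise FormatError(f"{path}: interval {name} has start {start} >= end {end}")
        out.append((chrom, start + 1, end, name))
    return out


def write_records(
    records: pd.DataFrame, path, seed: int | None = None, config: dict | None = None
) -> None:
    """Interaction-record table as TSV with one header line."""
    with Path(path).open("w") as fh:
        fh.write(_header_lines(seed, config))
        records.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA")


def write_network(
    net: nx.Graph, edges_path, graphml_path=None, seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Edge list (snp_a, snp_b, ig) as TSV; optionally GraphML alongside."""
    with Path(edges_path).open("w") as fh:
        fh.write(_header_lines(seed, config))
        fh.write("snp_a\tsnp_b\tig\n")
        for u, v, data in sorted(net.edges(data=True)):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{b}\t{data.get('ig', float('nan')):.10g}\n")
    if graphml_path is not None:
        nx.write_graphml(net, graphml_path)


def write_centrality(
    report: pd.DataFrame, path, seed: int | None = None, config: dict | None = None
) -> None:
    with Path(path).open("w") as fh:
        fh.write(_header_lines(seed, config))
        report.to_csv(fh, sep="\t", index=False)


def write_modules(
    modules, path, seed: int | None = None, config: dict | None = None
) -> None:
    """Module report: id, seed, score, members, genes involved."""
    with Path(path).open("w") as fh:
        fh.write(_header_lines(seed, config))
        fh.write("module_id\tseed\tscore\tn_members\tmembers\tgenes_involved\n")
        for i, mod in enumerate(modules, start=1):
            members = ",".join(sorted(mod.members))
            genes = ",".join(sorted(mod.genes_involved)) or "NULL"
            fh.write(f"{i}\t{mod.seed}\t{mod.score:.6g}\t{len(mod.members)}\t{members}\t{genes}\n")


def write_power_table(
    table: pd.DataFrame, path, seed: int | None = None, config: dict | None = None
) -> None:
    with Path(path).open("w") as fh:
        fh.write(_header_lines(seed, config))
        table.to_csv(fh, sep="\t", index=False)
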