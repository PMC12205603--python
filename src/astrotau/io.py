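"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: FASTA for protein sequences, TSV for
peptide-level quantification (PSM) tables, protein abundance matrices,
differential-expression tables and expression matrices, Newick for
dendrograms, and JSON for configuration, ground-truth sidecars and run
reports.  All readers validate their input and report errors with the
offending row or record; all writers are byte-deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

PSM_COLUMNS = ["sample_id", "peptide", "phospho_offsets", "precursor_abundance"]
DEG_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj"]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into an ordered accession -> sequence mapping.

    Sequences are uppercased; duplicate accessions, empty files and
    non-amino-acid characters are rejected.
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate accession in {path}: {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"record {rec.id!r} in {path} has non-amino-acid characters: {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSM tables


def parse_offsets(text) -> tuple[int, ...]:
    """Parse a semicolon-separated offset field; empty/missing means unmodified."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return ()
    return tuple(int(tok) for tok in str(text).split(";"))


def format_offsets(offsets) -> str:
    return ";".join(str(int(o)) for o in offsets)


def validate_psm_table(table: pd.DataFrame) -> None:
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PSM table missing required columns: {missing}")
    for idx, row in enumerate(table.itertuples(index=False), start=1):
        peptide = row.peptide
        if not peptide or not str(peptide).isupper():
            raise ValueError(f"PSM row {idx}: invalid peptide {peptide!r}")
        if row.precursor_abundance < 0:
            raise ValueError(
                f"PSM row {idx}: negative abundance {row.precursor_abundance}"
            )
        for off in row.phospho_offsets:
            if not 1 <= off <= len(peptide):
                raise ValueError(
                    f"PSM row {idx}: offset {off} outside peptide of length {len(peptide)}"
                )
            if peptide[off - 1] not in "STY":
                raise ValueError(
                    f"PSM row {idx}: phospho offset {off} on residue "
                    f"{peptide[off - 1]!r} (must be S/T/Y)"
                )


def read_psm_table(path) -> pd.DataFrame:
    """Read a PSM TSV; offsets become integer tuples, row order is preserved."""
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "peptide": str},
        keep_default_na=False,
        na_values=[],
    )
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: PSM table missing required columns: {missing}")
    table["phospho_offsets"] = table["phospho_offsets"].map(parse_offsets)
    table["precursor_abundance"] = pd.to_numeric(table["precursor_abundance"])
    validate_psm_table(table)
    return table[PSM_COLUMNS]


def write_psm_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["phospho_offsets"] = out["phospho_offsets"].map(format_offsets)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DEG tables and matrices


def read_deg_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: DEG table missing required columns: {missing}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    for col in ("pvalue", "padj"):
        vals = table[col].dropna()
        if ((vals <= 0) | (vals > 1)).any():
            raise ValueError(f"{path}: {col} values must lie in (0, 1]")
    return table[DEG_COLUMNS]


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a genes/proteins-as-rows, samples-as-columns TSV matrix."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row identifier {dup!r}")
    return matrix


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Newick export


def export_newick(tree, labels=None, precision: int = 10) -> str:
    """Serialize a hierarchical clustering as a rooted binary Newick string.

    Branch lengths are differences of merge heights (leaves sit at height 0),
    so parsing the string back recovers the original topology and, through
    root-to-leaf distances, the merge heights.
    """
    merges = np.asarray(tree.merges, dtype=float)
    labels = list(tree.leaf_labels if labels is None else labels)
    n = merges.shape[0] + 1
    if len(labels) != n:
        raise ValueError(f"expected {n} labels, got {len(labels)}")
    if len(set(labels)) != n:
        raise ValueError("leaf labels must be unique")

    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        a, b, h, _ = merges[node - n]
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        return (
            f"({render(a)}:{la:.{precision}g},{render(b)}:{lb:.{precision}g})"
        )

    for k, (_, _, h, _) in enumerate(merges):
        heights[n + k] = float(h)
    return render(2 * n - 2) + ";"


# ---------------------------------------------------------------------------
# Run reports


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunReport:
    """Machine-readable record of one pipeline invocation."""

    command: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: list = field(default_factory=list)

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        payload = {
            "command": self.command,
            "parameters": self.parameters,
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
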