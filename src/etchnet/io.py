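"""Plain-text readers and writers for the pipeline's file formats.

Everything on disk is TSV, BED, FASTA or JSON so that every intermediate
is diffable. Scoring tables use a SAINT-"list"-compatible layout so an
externally produced scoring file can be injected in place of the
internal scorer's output.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .scoring import SCORE_COLUMNS

#: external SAINT list column names -> internal ones
SAINT_ALIASES = {
    "Bait": "bait_id", "Prey": "prey_id", "AvgSpec": "avg_spec",
    "AvgP": "probability", "Probability": "probability", "BFDR": "bfdr",
    "FoldChange": "fold_change", "ctrlCounts": "control_avg",
}


def read_runs(path) -> pd.DataFrame:
    runs = pd.read_csv(path, sep="\t",
                       dtype={"prey_id": str, "bait_id": str})
    runs["is_control"] = runs["is_control"].astype(bool)
    return runs


def write_runs(runs: pd.DataFrame, path) -> None:
    runs.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    """Read a scoring TSV, accepting SAINT list headers as aliases."""
    frame = pd.read_csv(path, sep="\t")
    frame = frame.rename(columns=SAINT_ALIASES)
    missing = [c for c in ("bait_id", "prey_id", "avg_spec", "probability")
               if c not in frame.columns]
    if missing:
        raise ValueError(f"scoring table missing columns: {missing}")
    return frame


def write_scores(scored: pd.DataFrame, path) -> None:
    cols = [c for c in SCORE_COLUMNS if c in scored.columns]
    scored[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_repository_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"prey_id": str})


def write_repository(repo, path) -> None:
    repo.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bed(path) -> pd.DataFrame:
    """Read a 3+-column BED file (0-based, half-open)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    frame.columns = names[:frame.shape[1]] + list(frame.columns[6:])
    return frame


def write_bed(frame: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
            if c in frame.columns]
    frame[cols].to_csv(path, sep="\t", index=False, header=False)


def read_tss(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_markers(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
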