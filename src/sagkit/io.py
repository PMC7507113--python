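"""Plain-text readers/writers: FASTA (60-column wrapped) and TSV tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        records[name] = "".join(parts)
    return records


def parse_refdb_fasta(path) -> dict[str, tuple[str, str]]:
    """Read a 16S refdb FASTA with `>id;phylum=X` headers."""
    out: dict[str, tuple[str, str]] = {}
    name = None
    parts: list[str] = []

    def flush():
        if name is None:
            return
        rid, _, tag = name.partition(";phylum=")
        out[rid] = (tag or "unknown", "".join(parts))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                name = line[1:]
                parts = []
            elif line:
                parts.append(line)
    flush()
    return out


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        for k in sorted(config):
            fh.write(f"{k}={config[k]}\n")
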