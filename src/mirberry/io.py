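"""FASTA/FASTQ/TSV helpers shared across the pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO


def read_fasta(path) -> dict[str, str]:
    """id -> sequence (uppercased); descriptions are dropped."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_fasta_with_description(path) -> list[tuple[str, str, str]]:
    """(id, description, sequence) triples in file order."""
    return [
        (rec.id, rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_tsv(rows: Iterable[Iterable], path, header: Iterable[str] | None = None) -> None:
    with open(path, "w") as fh:
        if header is not None:
            fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# reference-collection persistence


def save_references(refs, directory) -> Path:
    """Write a ReferenceSets collection as plain FASTA/TSV files."""
    d = ensure_dir(directory)
    write_fasta(refs.cdna, d / "cdna.fasta")
    write_fasta(
        [(f"{m.identifier} family={m.family}", m.sequence) for m in refs.matures],
        d / "mature.fasta",
    )
    for cls, entries in refs.rfam.items():
        write_fasta(entries, d / f"rfam_{cls}.fasta")
    write_fasta(refs.ests, d / "est.fasta")
    for species, entries in refs.cross_species.items():
        write_fasta(entries, d / f"cross_{species}.fasta")
    write_tsv(refs.go_table, d / "go_table.tsv", header=("gene", "go_id"))
    write_tsv(
        sorted(refs.go_namespaces.items()),
        d / "go_namespaces.tsv",
        header=("go_id", "namespace"),
    )
    return d


def load_references(directory):
    """Load a ReferenceSets collection written by :func:`save_references`."""
    from .annotate import MatureRef, ReferenceSets

    d = Path(directory)
    refs = ReferenceSets()
    if (d / "cdna.fasta").exists():
        refs.cdna = read_fasta(d / "cdna.fasta")
    if (d / "mature.fasta").exists():
        for rec_id, desc, seq in read_fasta_with_description(d / "mature.fasta"):
            family = "unknown"
            for token in desc.split():
                if token.startswith("family="):
                    family = token.split("=", 1)[1]
            refs.matures.append(MatureRef(rec_id, family, seq.replace("T", "U")))
    for path in sorted(d.glob("rfam_*.fasta")):
        refs.rfam[path.stem.removeprefix("rfam_")] = read_fasta(path)
    if (d / "est.fasta").exists():
        refs.ests = read_fasta(d / "est.fasta")
    for path in sorted(d.glob("cross_*.fasta")):
        refs.cross_species[path.stem.removeprefix("cross_")] = read_fasta(path)
    if (d / "go_table.tsv").exists():
        with open(d / "go_table.tsv") as fh:
            next(fh)
            refs.go_table = [tuple(line.rstrip("\n").split("\t")) for line in fh]
    if (d / "go_namespaces.tsv").exists():
        with open(d / "go_namespaces.tsv") as fh:
            next(fh)
            refs.go_namespaces = dict(
                tuple(line.rstrip("\n").split("\t")) for line in fh
            )
    return refs
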