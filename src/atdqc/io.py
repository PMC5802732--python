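"""Readers and writers for the tabular/text formats the stages exchange."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .family import ProteinRecord
from .kinetics import TimeCourse
from .wobble import EnrichmentRow, TRNAGene

__all__ = [
    "read_fasta",
    "write_fasta",
    "genes_to_tsv",
    "enrichment_to_tsv",
    "timecourses_to_tsv",
    "read_timecourses",
    "read_presence",
    "presence_to_tsv",
]


def read_fasta(path) -> list[ProteinRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(tok.split("=", 1) for tok in rec.description.split() if "=" in tok)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                organism=fields.get("organism", ""),
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.organism:
                header += f" organism={rec.organism}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def genes_to_tsv(genes: Sequence[TRNAGene], path) -> None:
    df = pd.DataFrame(
        {
            "organism": [g.organism for g in genes],
            "isotype": [g.isotype for g in genes],
            "anticodon": [g.anticodon for g in genes],
            "score": [g.score for g in genes],
            "sequence": [g.sequence for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def enrichment_to_tsv(rows: Sequence[EnrichmentRow], path) -> None:
    df = pd.DataFrame(
        {
            "organism": [r.organism for r in rows],
            "isotype": [r.isotype for r in rows],
            "n_total": [r.n_total for r in rows],
            "n_wobble": [r.n_wobble for r in rows],
            "fraction": [r.fraction for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def timecourses_to_tsv(series: Sequence[TimeCourse], path) -> None:
    """Long-format kinetics table: substrate, enzyme_conc_nM, eftu, t_min,
    fraction_remaining."""
    rows = []
    for tc in series:
        for t, f in tc.points:
            rows.append(
                {
                    "substrate": tc.substrate,
                    "enzyme_conc_nM": tc.enzyme_conc,
                    "eftu": tc.eftu,
                    "t_min": t,
                    "fraction_remaining": f,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_timecourses(path) -> list[TimeCourse]:
    df = pd.read_csv(path, sep="\t")
    required = {"substrate", "enzyme_conc_nM", "eftu", "t_min", "fraction_remaining"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"kinetics table missing column(s): {sorted(missing)}")
    out = []
    for (sub, conc, eftu), grp in df.groupby(
        ["substrate", "enzyme_conc_nM", "eftu"], sort=True
    ):
        grp = grp.sort_values("t_min")
        out.append(
            TimeCourse(
                substrate=str(sub),
                enzyme_conc=float(conc),
                points=tuple(
                    zip(grp["t_min"].astype(float), grp["fraction_remaining"].astype(float))
                ),
                eftu=str(eftu),
            )
        )
    return out


def presence_to_tsv(presence: Mapping[str, bool], path) -> None:
    pd.DataFrame(
        {"organism": list(presence), "atd_present": [int(v) for v in presence.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_presence(path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    if "organism" not in df.columns or "atd_present" not in df.columns:
        raise ValueError("presence table needs columns: organism, atd_present")
    return {str(o): bool(int(p)) for o, p in zip(df["organism"], df["atd_present"])}
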