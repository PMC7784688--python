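"""Readers and writers for every file dialect the pipeline touches.

Formats: FASTA (DNA/protein, via Bio.SeqIO), BLAST-tabular homology hits
(qseqid, sseqid, pident, length, evalue, bitscore, qcovs, scovs), prophage
coordinate tables (TSV or GFF3), infection-matrix CSV, R-M and CRISPR
annotation TSVs, and capsule-trajectory CSV.

Conventions: FASTA identifiers are the first whitespace-delimited token of
the header and must be unique within a file; sequences are uppercased at
read time; all genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq import DNA_ALPHABET, PROTEIN_ALPHABET
from .types import (
    CRISPRArray,
    Completeness,
    HomologyHit,
    InfectionMatrix,
    Prophage,
    RMRole,
    RMSystem,
    RMType,
    Strain,
    Trajectory,
    Treatment,
)


class FastaRecord(NamedTuple):
    id: str
    sequence: str


_ALPHABETS = {"dna": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[FastaRecord]:
    """Read a FASTA file into ``(id, sequence)`` records in file order.

    The record id is the first whitespace token of the header; sequences are
    uppercased and validated against the declared alphabet (DNA: ACGTN;
    protein: 20 residues + X). Empty files and duplicate ids are errors.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"alphabet must be one of {sorted(_ALPHABETS)}")
    allowed = _ALPHABETS[alphabet]
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"record {rec.id!r}: illegal {alphabet} characters {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        records.append(FastaRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[FastaRecord | tuple[str, str]], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


HITS_COLUMNS = ["qseqid", "sseqid", "pident", "length", "evalue", "bitscore",
                "qcovs", "scovs"]


def read_hits_table(path: str | Path) -> list[HomologyHit]:
    """Read a BLAST-tabular hits TSV (8 columns, optional header row).

    Coverage columns are auto-detected as percents when any value exceeds 1
    and converted to fractions. Self-hits (query == subject) are dropped.
    Malformed rows raise with their line number.
    """
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "qseqid":
                continue  # header row
            if len(fields) != len(HITS_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(HITS_COLUMNS)} columns, got {len(fields)}"
                )
            rows.append((lineno, fields))

    parsed = []
    for lineno, f in rows:
        try:
            parsed.append((lineno, f[0], f[1], float(f[2]), int(float(f[3])),
                           float(f[4]), float(f[5]), float(f[6]), float(f[7])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None

    # Auto-detect percent coverages (0-100) vs fractions (0-1).
    cov_values = [v for _, *_rest, qc, sc in parsed for v in (qc, sc)]
    scale = 100.0 if cov_values and max(cov_values) > 1.0 else 1.0

    hits: list[HomologyHit] = []
    for lineno, q, s, pident, length, evalue, bits, qcov, scov in parsed:
        if q == s:
            continue  # self-hit
        try:
            hits.append(HomologyHit(
                query_id=q, subject_id=s, pct_identity=pident,
                query_coverage=qcov / scale, subject_coverage=scov / scale,
                evalue=evalue, bitscore=bits, alignment_length=length,
            ))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_hits_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HITS_COLUMNS)
        for h in hits:
            w.writerow([h.query_id, h.subject_id, f"{h.pct_identity:.3f}",
                        h.alignment_length or 0, f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}", f"{h.query_coverage:.4f}",
                        f"{h.subject_coverage:.4f}"])


def read_prophage_table(path: str | Path) -> list[Prophage]:
    """Read prophage coordinates/metadata from TSV or GFF3 (by extension).

    GFF3: features of type ``prophage``; completeness is the ``phaster_class``
    attribute. TSV: columns prophage_id, strain_id, start, end, completeness.
    Coordinates are 1-based inclusive in both dialects.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_prophage_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"prophage_id", "strain_id", "start", "end", "completeness"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        Prophage(
            prophage_id=row.prophage_id, host_strain_id=row.strain_id,
            start=int(row.start), end=int(row.end),
            completeness=Completeness(row.completeness),
        )
        for row in df.itertuples()
    ]


def _read_prophage_gff3(path: Path) -> list[Prophage]:
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    prophages = []
    for feat in db.features_of_type("prophage", order_by=("seqid", "start")):
        attrs = dict(feat.attributes)
        pid = attrs.get("ID", [feat.id])[0]
        completeness = attrs.get("phaster_class", ["intact"])[0]
        prophages.append(Prophage(
            prophage_id=pid, host_strain_id=feat.seqid,
            start=feat.start, end=feat.end,
            completeness=Completeness(completeness),
        ))
    return prophages


def read_infection_matrix(path: str | Path, n_replicates: int = 3) -> InfectionMatrix:
    """Read the infection-matrix CSV: first column producer ids, header row
    target ids, integer replicate-count cells."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer cell ({exc})") from None
    return InfectionMatrix(counts=df, n_replicates=n_replicates)


def write_infection_matrix(matrix: InfectionMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, index_label="producer")


def read_strain_table(path: str | Path) -> list[Strain]:
    """Read strain metadata TSV: strain_id plus optional species, clt,
    lps_type, chromosome_gc, bacteriocin_status columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "strain_id" not in df.columns:
        raise ValueError(f"{path}: missing column strain_id")
    strains = []
    for row in df.itertuples():
        kwargs: dict = {"strain_id": row.strain_id}
        for col in ("species", "clt", "lps_type"):
            val = getattr(row, col, None)
            if isinstance(val, str) and val:
                kwargs[col] = val
        gc = getattr(row, "chromosome_gc", None)
        if isinstance(gc, str) and gc:
            kwargs["chromosome_gc"] = float(gc)
        bact = getattr(row, "bacteriocin_status", None)
        if isinstance(bact, str) and bact:
            kwargs["bacteriocin_status"] = bact
        strains.append(Strain(**kwargs))
    ids = [s.strain_id for s in strains]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate strain ids")
    return strains


def write_strain_table(strains: Iterable[Strain], path: str | Path) -> None:
    rows = [{
        "strain_id": s.strain_id, "species": s.species, "clt": s.clt,
        "lps_type": s.lps_type,
        "chromosome_gc": "" if s.chromosome_gc is None else f"{s.chromosome_gc:.4f}",
        "bacteriocin_status": s.bacteriocin_status.value,
    } for s in strains]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rm_table(path: str | Path,
                  protein_seqs: Mapping[str, str] | None = None) -> list[RMSystem]:
    """Read the R-M TSV (system_id, strain_id, rm_type, role,
    protein_fasta_id, motif), one row per component; component protein
    sequences are resolved through ``protein_seqs`` when provided."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"system_id", "strain_id", "rm_type", "role", "protein_fasta_id", "motif"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    systems: dict[str, RMSystem] = {}
    for row in df.itertuples():
        seq = ""
        if protein_seqs is not None and row.protein_fasta_id:
            try:
                seq = protein_seqs[row.protein_fasta_id]
            except KeyError:
                raise ValueError(
                    f"{path}: protein {row.protein_fasta_id!r} not in provided FASTA"
                ) from None
        if row.system_id not in systems:
            systems[row.system_id] = RMSystem(
                system_id=row.system_id, strain_id=row.strain_id,
                rm_type=RMType(row.rm_type), components=[],
                recognition_motif=row.motif or None,
            )
        sys_obj = systems[row.system_id]
        if seq:
            sys_obj.components.append((RMRole(row.role), seq.upper()))
        else:
            sys_obj.components.append((RMRole(row.role), "X"))
        if row.motif and sys_obj.recognition_motif is None:
            sys_obj.recognition_motif = row.motif.upper()
    return list(systems.values())


def write_rm_table(systems: Iterable[RMSystem], path: str | Path,
                   protein_ids: Mapping[tuple[str, int], str] | None = None) -> None:
    rows = []
    for s in systems:
        for i, (role, _seq) in enumerate(s.components):
            pid = protein_ids.get((s.system_id, i), f"{s.system_id}_{role.value}_{i}") \
                if protein_ids else f"{s.system_id}_{role.value}_{i}"
            rows.append({
                "system_id": s.system_id, "strain_id": s.strain_id,
                "rm_type": s.rm_type.value, "role": role.value,
                "protein_fasta_id": pid, "motif": s.recognition_motif or "",
            })
    pd.DataFrame(rows, columns=["system_id", "strain_id", "rm_type", "role",
                                "protein_fasta_id", "motif"]).to_csv(
        path, sep="\t", index=False)


def read_crispr_table(path: str | Path) -> list[CRISPRArray]:
    """Read the CRISPR TSV (array_id, strain_id, spacer_seq), one spacer per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"array_id", "strain_id", "spacer_seq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    arrays: dict[str, CRISPRArray] = {}
    for row in df.itertuples():
        if row.array_id not in arrays:
            arrays[row.array_id] = CRISPRArray(
                array_id=row.array_id, strain_id=row.strain_id, spacers=[])
        arrays[row.array_id].spacers.append(row.spacer_seq.upper())
    return list(arrays.values())


def write_crispr_table(arrays: Iterable[CRISPRArray], path: str | Path) -> None:
    rows = [{"array_id": a.array_id, "strain_id": a.strain_id, "spacer_seq": sp}
            for a in arrays for sp in a.spacers]
    pd.DataFrame(rows, columns=["array_id", "strain_id", "spacer_seq"]).to_csv(
        path, sep="\t", index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read the trajectory CSV (population_id, strain_id, treatment, day,
    capsulated_fraction) into per-population day->fraction maps."""
    df = pd.read_csv(path, dtype={"population_id": str, "strain_id": str,
                                  "treatment": str})
    required = {"population_id", "strain_id", "treatment", "day", "capsulated_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[Trajectory] = []
    for (pop, strain, treat), grp in df.groupby(
            ["population_id", "strain_id", "treatment"], sort=False):
        values = {int(d): float(f) for d, f in
                  zip(grp["day"], grp["capsulated_fraction"])}
        out.append(Trajectory(population_id=pop, strain_id=strain,
                              treatment=Treatment(treat), values=values))
    return out


def write_trajectories(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    rows = [{"population_id": t.population_id, "strain_id": t.strain_id,
             "treatment": t.treatment.value, "day": day,
             "capsulated_fraction": f"{t.values[day]:.6f}"}
            for t in trajectories for day in t.days]
    pd.DataFrame(rows, columns=["population_id", "strain_id", "treatment", "day",
                                "capsulated_fraction"]).to_csv(path, index=False)
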