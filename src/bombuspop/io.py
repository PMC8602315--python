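"""Readers and writers: GenePop genotypes, specimen metadata CSV, FASTA.

GenePop is the exchange format used for the codominant genotypes; both the
2-digit and 3-digit allele codings are supported and auto-detected per file.
Writers emit a deterministic ordering (specimen id within population, locus
order of the panel) so round-trips are bit-stable.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    Era,
    GenotypeCall,
    Haplotype,
    LocusDef,
    Morphotype,
    PopulationSample,
    Sex,
    Specimen,
)


class GenePopParseError(ValueError):
    pass


def _decode_token(token: str, locus: str, digits: int) -> GenotypeCall:
    if len(token) == 2 * digits:
        raw = [token[:digits], token[digits:]]
    elif len(token) == digits:
        raw = [token]  # haploid call
    else:
        raise GenePopParseError(
            f"genotype token {token!r} at locus {locus} is neither "
            f"{digits}- nor {2 * digits}-digit"
        )
    alleles = [int(r) for r in raw if int(r) != 0]
    return GenotypeCall(locus=locus, alleles=tuple(alleles))


def _detect_digits(tokens: list[str]) -> int:
    lengths = {len(t) for t in tokens}
    if lengths <= {3, 6}:
        return 3
    if lengths <= {2, 4}:
        return 2
    raise GenePopParseError(f"cannot auto-detect allele coding from token lengths {lengths}")


def read_genepop(path: str | Path) -> tuple[list[LocusDef], list[PopulationSample]]:
    """Parse a GenePop file into a locus panel and population samples.

    Specimen ids are taken from the line labels; ``00``/``000`` decodes to a
    missing call (empty multiset).  Populations are named after the id prefix
    of their first member when it looks like ``CODE_nn``, else ``pop<i>``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenePopParseError(f"{path}: empty file (missing header)")
    # line 0: title.  Locus names: one per line, or comma-separated on one line.
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if not part:
            i += 1
            continue
        if "," in part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        else:
            loci.append(part)
        i += 1
    if i == len(lines):
        raise GenePopParseError(f"{path}: no 'POP' separator found (line {i})")
    if not loci:
        raise GenePopParseError(f"{path}: no locus names before first 'POP' (line {i + 1})")

    populations: list[PopulationSample] = []
    current: list[Specimen] = []
    digits: int | None = None

    def close_pop() -> None:
        nonlocal current
        if current:
            first = current[0].id
            code = first.rsplit("_", 1)[0] if "_" in first else f"pop{len(populations) + 1}"
            for s in current:
                s.location = code
            populations.append(PopulationSample(code=code, specimens=list(current)))
            current = []

    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            close_pop()
            continue
        if "," not in line:
            raise GenePopParseError(f"{path}:{lineno + 1}: expected 'id , genotypes'")
        label, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenePopParseError(
                f"{path}:{lineno + 1}: specimen {label.strip()!r} has {len(tokens)} "
                f"genotypes for a {len(loci)}-locus panel"
            )
        if digits is None:
            digits = _detect_digits(tokens)
        calls = [_decode_token(t, loci[k], digits) for k, t in enumerate(tokens)]
        sex = Sex.MALE if all(len(c.alleles) <= 1 for c in calls) else Sex.FEMALE
        current.append(
            Specimen(id=label.strip(), location="", sex=sex, genotypes=calls)
        )
    close_pop()

    domains: dict[str, set[int]] = {n: set() for n in loci}
    for pop in populations:
        for s in pop.specimens:
            for c in s.genotypes:
                domains[c.locus].update(c.alleles)
    panel = [LocusDef(name=n, allele_domain=frozenset(domains[n])) for n in loci]
    return panel, populations


def write_genepop(
    path: str | Path,
    panel: list[LocusDef],
    populations: Iterable[PopulationSample],
    title: str = "bombuspop export",
    digits: int = 3,
) -> None:
    def enc(call: GenotypeCall | None) -> str:
        missing = "0" * digits
        if call is None or call.is_missing:
            return missing * 2
        alleles = list(call.alleles)[:2]
        # hemizygous calls keep the single-token haploid coding so the
        # genotype matrix round-trips exactly
        return "".join(f"{a:0{digits}d}" for a in alleles)

    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in panel:
            fh.write(locus.name + "\n")
        for pop in populations:
            fh.write("POP\n")
            for s in sorted(pop.specimens, key=lambda s: s.id):
                row = " ".join(enc(s.genotype_at(l.name)) for l in panel)
                fh.write(f"{s.id} , {row}\n")


METADATA_COLUMNS = ["id", "location", "sex", "morphotype", "haplotype", "era"]


def _enum_or_unknown(cls, value: str):
    try:
        return cls(value)
    except ValueError:
        return cls.UNKNOWN


def read_metadata(path: str | Path) -> dict[str, Specimen]:
    """Read the specimen metadata CSV (UTF-8, header row).

    Unknown category strings are read as ``unknown`` rather than dropped.
    """
    out: dict[str, Specimen] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(METADATA_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
        for row in reader:
            sid = row["id"]
            if sid in out:
                raise ValueError(f"{path}: duplicate specimen id {sid!r}")
            out[sid] = Specimen(
                id=sid,
                location=row["location"],
                sex=Sex(row["sex"]),
                morphotype=_enum_or_unknown(Morphotype, row["morphotype"]),
                haplotype=_enum_or_unknown(Haplotype, row["haplotype"]),
                era=_enum_or_unknown(Era, row["era"]) if row["era"] else Era.CURRENT,
            )
    return out


def write_metadata(path: str | Path, specimens: Iterable[Specimen]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for s in sorted(specimens, key=lambda s: s.id):
            writer.writerow(
                [s.id, s.location, s.sex.value, s.morphotype.value, s.haplotype.value, s.era.value]
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def attach_metadata(
    populations: list[PopulationSample], metadata: dict[str, Specimen]
) -> list[PopulationSample]:
    """Merge metadata records into genotyped specimens (matched on id)."""
    for pop in populations:
        for s in pop.specimens:
            meta = metadata.get(s.id)
            if meta is None:
                continue
            s.location = meta.location
            s.sex = meta.sex
            s.morphotype = meta.morphotype
            s.haplotype = meta.haplotype
            s.era = meta.era
    return populations


def _open_maybe(path_or_handle: str | Path | TextIO, mode: str = "r"):
    if hasattr(path_or_handle, "write") or hasattr(path_or_handle, "read"):
        return path_or_handle
    return open(path_or_handle, mode)
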