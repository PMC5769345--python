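"""Readers and writers: FASTA, XMFA, MAF and the consensus index bundle.

The XMFA dialect is Mauve-style: "> seqnum:start-end strand name" headers,
"=" terminating each block, "0-0" for canonical empty entries, and "#"
metadata lines carrying genome names and replicon layouts.  The index
bundle is a plain tab-separated text file with sentinel section headers so
the pan-genome stays diffable; its layout is this package's own.

All writers are deterministic: identical data model, identical bytes.
Reading is gzip-transparent.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path

from Bio import SeqIO

from .datamodel import (
    Block,
    FormatError,
    GenomeAlignment,
    GenomeRecord,
    SequenceEntry,
    require_valid,
)
from .consensus import BlockCoords, ConsensusGenome, ConsensusIndexBundle


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """(description, sequence) for every record; gzip transparent."""
    with _open_text(path) as fh:
        return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: list[tuple[str, str]], path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


# -- XMFA -------------------------------------------------------------------

_XMFA_HEADER = re.compile(
    r"^>\s*(\d+):(\d+)-(\d+)\s+([+-])(?:\s+(.*))?$")


def serialize_xmfa(a: GenomeAlignment, wrap: int = 80) -> str:
    """Mauve-style XMFA text for an alignment (validates first)."""
    require_valid(a)
    lines = ["#FormatVersion seqpan 1",
             f"#SequenceCount {len(a.genomes)}"]
    for g in sorted(a.genomes, key=lambda g: g.genome_id):
        lines.append(f"#Sequence{g.genome_id}Name\t{g.name}")
        lines.append(f"#Sequence{g.genome_id}Length\t{g.total_length}")
        reps = ";".join(f"{rn}:{ln}" for rn, ln in g.replicons)
        lines.append(f"#Sequence{g.genome_id}Replicons\t{reps}")
    for block in a.blocks:
        for e in block.entries:
            name = a.genome(e.genome_id).name
            lines.append(f"> {e.genome_id}:{e.start}-{e.end} {e.strand} {name}")
            for i in range(0, len(e.text), wrap):
                lines.append(e.text[i:i + wrap])
        lines.append("=")
    return "\n".join(lines) + "\n"


def parse_xmfa(text: str) -> GenomeAlignment:
    """Parse Mauve-style XMFA text into the data model.

    Coordinates are taken verbatim (1-based inclusive); "0-0" headers
    become canonical empty entries and blocks with no non-empty entry are
    dropped.  Genome metadata comes from the "#" preamble when present and
    is otherwise inferred from coverage.
    """
    meta_name: dict[int, str] = {}
    meta_len: dict[int, int] = {}
    meta_reps: dict[int, list[tuple[str, int]]] = {}
    blocks: list[Block] = []
    entries: list[SequenceEntry] = []
    seq_parts: list[str] = []
    current: tuple[int, int, int, str] | None = None

    def flush_entry():
        nonlocal current
        if current is None:
            return
        gid, s, e, strand = current
        text_ = "".join(seq_parts)
        seq_parts.clear()
        if s == 0 and e == 0:
            entry = SequenceEntry(gid, 0, 0, strand, text_)
            if entry.nongap_length:
                raise FormatError(f"0-0 entry for genome {gid} carries sequence")
        else:
            entry = SequenceEntry(gid, s, e, strand, text_)
            if entry.nongap_length != e - s + 1:
                raise FormatError(
                    f"genome {gid}: {entry.nongap_length} non-gap characters "
                    f"inconsistent with coordinates {s}-{e}")
        if any(x.genome_id == gid for x in entries):
            raise FormatError(f"duplicate genome {gid} within one block")
        entries.append(entry)
        current = None

    def flush_block():
        flush_entry()
        nonempty = [e for e in entries if not e.is_empty]
        if nonempty:
            widths = {len(e.text) for e in nonempty}
            if len(widths) != 1:
                raise FormatError("entries of one block differ in length")
            tag = "aligned" if len(nonempty) > 1 else "single_sequence"
            blocks.append(Block(list(nonempty), tag=tag))
        entries.clear()

    for raw in text.splitlines():
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"^#Sequence(\d+)(Name|Length|Replicons)\t?(.*)$", line)
            if m:
                gid = int(m.group(1))
                val = m.group(3).strip()
                if m.group(2) == "Name":
                    meta_name[gid] = val
                elif m.group(2) == "Length":
                    meta_len[gid] = int(val)
                else:
                    reps = []
                    for part in val.split(";"):
                        if part:
                            rn, _, ln = part.rpartition(":")
                            reps.append((rn, int(ln)))
                    meta_reps[gid] = reps
            continue
        if line.startswith(">"):
            flush_entry()
            m = _XMFA_HEADER.match(line)
            if not m:
                raise FormatError(f"malformed XMFA header: {line!r}")
            current = (int(m.group(1)), int(m.group(2)), int(m.group(3)),
                       m.group(4))
            continue
        if line.startswith("="):
            flush_block()
            continue
        seq_parts.append(line)
    flush_block()

    gids = sorted({e.genome_id for b in blocks for e in b.entries} | set(meta_name))
    genomes = []
    for gid in gids:
        name = meta_name.get(gid, f"seq{gid}")
        if gid in meta_reps:
            reps = meta_reps[gid]
        else:
            length = meta_len.get(gid)
            if length is None:
                length = max((e.end for b in blocks for e in b.entries
                              if e.genome_id == gid), default=0)
            reps = [(name, length)]
        genomes.append(GenomeRecord(gid, name, reps))
    return GenomeAlignment(genomes, blocks)


def load_xmfa(path) -> GenomeAlignment:
    with _open_text(path) as fh:
        return parse_xmfa(fh.read())


def write_xmfa(a: GenomeAlignment, path, wrap: int = 80) -> None:
    Path(path).write_text(serialize_xmfa(a, wrap))


# -- MAF --------------------------------------------------------------------

def _maf_src(name: str, replicon: str) -> str:
    base = name.split()[0] if name.split() else "seq"
    rep = replicon.split()[0] if replicon.split() else "chr"
    return f"{base}.{rep}" if rep != base else base


def serialize_maf(a: GenomeAlignment) -> str:
    """Standard MAF: 0-based starts on the strand of the text, sizes in
    ungapped bases, source sizes per replicon."""
    require_valid(a)
    lines = ["##maf version=1 scoring=none", ""]
    for block in a.blocks:
        lines.append("a")
        for e in block.entries:
            g = a.genome(e.genome_id)
            rep_name, local_start = g.locate(e.start)
            rep_name_end, local_end = g.locate(e.end)
            if rep_name != rep_name_end:
                raise FormatError(
                    f"entry {e.start}-{e.end} of genome {e.genome_id} spans "
                    "replicons and cannot be written as MAF")
            src_size = dict(g.replicons)[rep_name]
            size = e.nongap_length
            if e.strand == "+":
                start = local_start - 1
            else:
                start = src_size - local_end
            lines.append(
                f"s {_maf_src(g.name, rep_name)} {start} {size} {e.strand} "
                f"{src_size} {e.text}")
        lines.append("")
    return "\n".join(lines) + "\n"


def write_maf(a: GenomeAlignment, path) -> None:
    Path(path).write_text(serialize_maf(a))


def parse_maf(text: str) -> GenomeAlignment:
    """Parse MAF produced by this package (single-replicon sources)."""
    blocks: list[Block] = []
    entries: list[SequenceEntry] = []
    ids: dict[str, int] = {}
    sizes: dict[str, int] = {}

    def flush():
        if entries:
            blocks.append(Block(list(entries),
                                tag="aligned" if len(entries) > 1 else "single_sequence"))
            entries.clear()

    for line in text.splitlines():
        if line.startswith("a"):
            flush()
        elif line.startswith("s "):
            _, src, start, size, strand, src_size, seq = line.split()
            start, size, src_size = int(start), int(size), int(src_size)
            gid = ids.setdefault(src, len(ids) + 1)
            sizes[src] = src_size
            if strand == "+":
                s, e = start + 1, start + size
            else:
                e = src_size - start
                s = e - size + 1
            entries.append(SequenceEntry(gid, s, e, strand, seq))
    flush()
    genomes = [GenomeRecord(gid, src, [(src, sizes[src])])
               for src, gid in sorted(ids.items(), key=lambda kv: kv[1])]
    return GenomeAlignment(genomes, blocks)


# -- consensus index bundle -------------------------------------------------

def write_index_bundle(bundle: ConsensusIndexBundle, path) -> None:
    lines = ["#meta",
             f"delimiter_length\t{bundle.delimiter_length}",
             f"source\t{bundle.source_ref}"]
    lines.append("#delimiters")
    for s, ln in bundle.delimiter_index:
        lines.append(f"{s}\t{ln}")
    lines.append("#blocks")
    for bi, row in enumerate(bundle.block_table):
        for gid in sorted(row.coords):
            s, e, strand = row.coords[gid]
            lines.append(f"{bi}\t{row.cons_start}\t{row.cons_end}\t{gid}\t{s}\t{e}\t{strand}")
    lines.append("#gaps")
    for bi, gaps in enumerate(bundle.gap_index):
        for gid in sorted(gaps):
            for col, ln in gaps[gid]:
                lines.append(f"{bi}\t{gid}\t{col}\t{ln}")
    lines.append("#genomes")
    for gid in sorted(bundle.genome_table):
        g = bundle.genome_table[gid]
        reps = ";".join(f"{rn}:{ln}" for rn, ln in g.replicons)
        lines.append(f"{gid}\t{g.name}\t{reps}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_index_bundle(path) -> ConsensusIndexBundle:
    sections: dict[str, list[str]] = {}
    section = None
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                section = line[1:]
                if section in sections:
                    raise FormatError(f"duplicate section #{section}")
                sections[section] = []
                continue
            if section is None:
                raise FormatError("content before any section header")
            sections[section].append(line)
    for required in ("delimiters", "blocks", "gaps", "genomes"):
        if required not in sections:
            raise FormatError(f"missing section #{required}")

    meta = dict(line.split("\t", 1) for line in sections.get("meta", []))
    delimiter_length = int(meta.get("delimiter_length", 1000))

    delimiter_index = []
    prev = 0
    for line in sections["delimiters"]:
        s, ln = (int(x) for x in line.split("\t"))
        if s <= prev:
            raise FormatError("section #delimiters is not sorted")
        delimiter_index.append((s, ln))
        prev = s

    rows: dict[int, BlockCoords] = {}
    for line in sections["blocks"]:
        bi, cs, ce, gid, s, e, strand = line.split("\t")
        bi = int(bi)
        row = rows.setdefault(bi, BlockCoords(int(cs), int(ce), {}))
        row.coords[int(gid)] = (int(s), int(e), strand)
    block_table = [rows[bi] for bi in sorted(rows)]

    gap_index: list[dict[int, list[tuple[int, int]]]] = [
        {} for _ in block_table]
    for line in sections["gaps"]:
        bi, gid, col, ln = (int(x) for x in line.split("\t"))
        gap_index[bi].setdefault(gid, []).append((col, ln))

    genome_table = {}
    for line in sections["genomes"]:
        gid, name, reps = line.split("\t")
        replicons = []
        for part in reps.split(";"):
            if part:
                rn, _, ln = part.rpartition(":")
                replicons.append((rn, int(ln)))
        genome_table[int(gid)] = GenomeRecord(int(gid), name, replicons)

    return ConsensusIndexBundle(
        delimiter_index=delimiter_index,
        gap_index=gap_index,
        block_table=block_table,
        genome_table=genome_table,
        delimiter_length=delimiter_length,
        source_ref=meta.get("source", ""),
    )


# -- consensus genome -------------------------------------------------------

def write_consensus(c: ConsensusGenome, fasta_path, bundle_path,
                    wrap: int = 80) -> None:
    header = (f"consensus delimiter_length={c.delimiter_length} "
              f"source={c.source_ref}")
    write_fasta([(header, c.sequence)], fasta_path, wrap)
    write_index_bundle(c.index, bundle_path)


def load_consensus(fasta_path, bundle_path,
                   source_alignment: GenomeAlignment | None = None) -> ConsensusGenome:
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise FormatError("consensus FASTA must hold exactly one record")
    header, seq = records[0]
    bundle = parse_index_bundle(bundle_path)
    m = re.search(r"delimiter_length=(\d+)", header)
    delim = int(m.group(1)) if m else bundle.delimiter_length
    return ConsensusGenome(seq, delim, bundle,
                           source_alignment=source_alignment,
                           source_ref=bundle.source_ref)
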