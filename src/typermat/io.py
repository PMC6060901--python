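"""File formats: PHYLIP square distance matrices, FASTA families, NEXUS
splits, and TSV event/posterior tables.

The label order of every format is meaningful — it encodes the genomic gene
order — and is preserved on round trips.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distmat import DistanceMatrix
from .seqsim import AMINO_ACIDS, SequenceFamily
from .splits import SplitSystem

__all__ = [
    "read_phylip_dist",
    "write_phylip_dist",
    "read_fasta",
    "write_fasta",
    "write_nexus_splits",
    "write_event_log",
    "write_recognition_events",
]

MAX_LABEL = 64


def read_phylip_dist(path, *, sym_tol: float = 1e-6) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (relaxed labels, <= 64 chars).

    First line: the number of taxa. Each row: a label followed by n
    whitespace-separated distances (rows may wrap across lines). Slight
    asymmetry up to `sym_tol` is symmetrized with a warning; worse
    asymmetry is an error.
    """
    text = Path(path).read_text()
    tokens = text.split()
    if not tokens:
        raise ValueError("empty distance file")
    try:
        n = int(tokens[0])
    except ValueError:
        raise ValueError(f"malformed header {tokens[0]!r}: expected the taxon count")
    if len(tokens) != 1 + n * (n + 1):
        raise ValueError(
            f"expected {n} rows of a label plus {n} values each "
            f"({n * (n + 1)} tokens), found {len(tokens) - 1}"
        )
    labels, rows = [], []
    pos = 1
    for _ in range(n):
        lab = tokens[pos]
        if len(lab) > MAX_LABEL:
            raise ValueError(f"label {lab!r} exceeds {MAX_LABEL} characters")
        labels.append(lab)
        try:
            rows.append([float(v) for v in tokens[pos + 1 : pos + 1 + n]])
        except ValueError as e:
            raise ValueError(f"non-numeric distance in row {lab!r}: {e}") from None
        pos += 1 + n
    m = np.array(rows)
    asym = np.max(np.abs(m - m.T))
    if asym > sym_tol:
        raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g} > {sym_tol})")
    if asym > 0:
        warnings.warn(f"symmetrizing matrix (max asymmetry {asym:.3g})")
        m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels, m)


def write_phylip_dist(D: DistanceMatrix, path) -> None:
    """Write a square PHYLIP distance matrix (17 significant digits)."""
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for lab, row in zip(D.labels, D.values):
            vals = " ".join(format(v, ".17g") for v in row)
            fh.write(f"{lab} {vals}\n")


def read_fasta(
    path, *, alphabet: str = AMINO_ACIDS, allow_gaps: bool = False
) -> SequenceFamily:
    """Read an aligned FASTA file into a :class:`SequenceFamily`.

    Record order is preserved (it encodes the genomic order); sequences must
    have equal length and use only `alphabet` residues (plus ``-`` with
    `allow_gaps`, in which case the gap becomes an extra alphabet symbol).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if allow_gaps and "-" not in alphabet:
        alphabet = alphabet + "-"
    lut = {ch: i for i, ch in enumerate(alphabet)}
    labels, rows = [], []
    length = None
    for rec in records:
        s = str(rec.seq).upper()
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise ValueError(
                f"record {rec.id!r} has length {len(s)}, expected {length}"
            )
        bad = set(s) - set(alphabet)
        if bad:
            raise ValueError(f"record {rec.id!r} has illegal residues {sorted(bad)}")
        labels.append(rec.id)
        rows.append([lut[ch] for ch in s])
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate record identifiers")
    return SequenceFamily(
        labels=tuple(labels), sequences=np.array(rows, dtype=np.int64),
        alphabet=alphabet,
    )


def write_fasta(F: SequenceFamily, path, *, width: int = 60) -> None:
    """Write a :class:`SequenceFamily` to FASTA, preserving genomic order."""
    strings = F.as_strings()
    records = [
        SeqRecord(Seq(strings[lab]), id=lab, description="") for lab in F.labels
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_nexus_splits(S: SplitSystem, path) -> None:
    """Export a split system as a SplitsTree4-compatible NEXUS file.

    Writes TAXA and SPLITS blocks (with a CYCLE statement); weights are the
    isolation indices at 10 significant digits. Loadable by SplitsTree for
    visual comparison with split networks of real clusters.
    """
    order = S.order
    n = len(order)
    idx = {lab: i + 1 for i, lab in enumerate(order)}
    buf = _io.StringIO()
    buf.write("#NEXUS\n\n")
    buf.write("BEGIN Taxa;\n")
    buf.write(f"DIMENSIONS ntax={n};\n")
    buf.write("TAXLABELS\n")
    for i, lab in enumerate(order, 1):
        buf.write(f"[{i}] '{lab}'\n")
    buf.write(";\nEND; [Taxa]\n\n")
    buf.write("BEGIN Splits;\n")
    buf.write(f"DIMENSIONS ntax={n} nsplits={len(S.splits)};\n")
    buf.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
    buf.write("PROPERTIES fit=-1.0 cyclic;\n")
    buf.write("CYCLE " + " ".join(str(i) for i in range(1, n + 1)) + ";\n")
    buf.write("MATRIX\n")
    for k, s in enumerate(S.splits, 1):
        members = " ".join(str(idx[lab]) for lab in s.block)
        buf.write(f"[{k}, size={len(s.block)}] \t {s.alpha:.10g} \t {members},\n")
    buf.write(";\nEND; [Splits]\n")
    Path(path).write_text(buf.getvalue())


def _fmt_config(cfg) -> str:
    if cfg is None:
        return "{}"
    if hasattr(cfg, "__dataclass_fields__"):
        return json.dumps(
            {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}, default=str
        )
    return json.dumps(cfg, default=str)


def write_event_log(log, path) -> None:
    """Write a simulator event log as TSV (one event per row).

    Columns: time, kind, parents (';'-joined), child, a, breakpoint, deltas
    ('label:value;...'). Header comments echo the config and seed.
    """
    with open(path, "w") as fh:
        fh.write(f"# seed={log.seed}\n")
        fh.write(f"# config={_fmt_config(getattr(log, 'config', None))}\n")
        fh.write(f"# genomic_order={','.join(log.genomic_order)}\n")
        fh.write("time\tkind\tparents\tchild\ta\tbreakpoint\tdeltas\n")
        for e in log.events:
            parents = ";".join(e.parents)
            child = ";".join(e.children()) if hasattr(e, "children") else e.child
            a = "" if e.a is None else format(e.a, ".17g")
            bp = getattr(e, "breakpoint", None)
            deltas = getattr(e, "deltas", None)
            dcol = (
                ";".join(f"{k}:{format(v, '.17g')}" for k, v in deltas.items())
                if deltas
                else ""
            )
            fh.write(
                f"{e.time_index}\t{e.kind}\t{parents}\t{child}\t{a}\t"
                f"{'' if bp is None else bp}\t{dcol}\n"
            )


def write_recognition_events(result, path) -> None:
    """Write recovered events as TSV mirroring the simulator's schema."""
    with open(path, "w") as fh:
        fh.write(f"# is_type_r={result.is_type_r} tol={result.tol}\n")
        if result.box is not None:
            fh.write(
                "# terminal_circular_order="
                + ",".join(result.box.circular_order)
                + "\n"
            )
        fh.write(
            "peel_index\tkind\tx\ty\tz\ta\tdelta_x\tdelta_y\tdelta_z\t"
            "d_xy_ancestral\tresidual\n"
        )
        for i, ev in enumerate(result.events):
            fh.write(
                f"{i}\t{ev.kind}\t{ev.x}\t{ev.y or ''}\t{ev.z}\t"
                f"{ev.a:.17g}\t{ev.delta_x:.17g}\t{ev.delta_y:.17g}\t"
                f"{ev.delta_z:.17g}\t{ev.d_xy_ancestral:.17g}\t{ev.residual:.3g}\n"
            )
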