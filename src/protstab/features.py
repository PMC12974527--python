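"""Per-protein feature assembly for the stability classifier.

Sequence-derived features are computed with Biopython's ProtParam
machinery: length, molecular weight, isoelectric point, GRAVY
hydropathy, aromaticity, the 20 amino-acid composition fractions,
one-hot encodings of the N-terminal residue (after the initiator-Met
removal rule) and of the C-terminal residue, and binary degron-motif
flags scanned against the first and last 25 residues.  Degron motifs
use a tiny anchored pattern language: a leading ``^`` pins the motif to
the very N terminus, a trailing ``$`` to the very C terminus, and ``X``
is a single-residue wildcard.

External knowledge-base tables (UniProt / EcoCyc / STRING / AlphaFold
exports, supplied as TSVs keyed by protein id) are left-joined onto the
sequence core; absent values stay missing and each external column gets
a paired missingness indicator.  A reduced mode drops all
external-provenance columns so the classifier can run from sequence
alone.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import ConfigError, InputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
TERMINAL_WINDOW = 25


def _motif_to_regex(motif: str) -> tuple[str, str]:
    """Translate a degron motif to (anchor, regex). anchor in {n, c, any}."""
    anchor = "any"
    body = motif.strip()
    if body.startswith("^"):
        anchor, body = "n", body[1:]
    if body.endswith("$"):
        if anchor == "n":
            raise ConfigError(f"motif {motif!r} anchored at both termini")
        anchor, body = "c", body[:-1]
    if not body or not re.fullmatch(r"[A-Za-z]+", body.replace("X", "A")):
        raise ConfigError(f"invalid degron motif {motif!r}")
    regex = "".join("." if ch == "X" else re.escape(ch) for ch in body.upper())
    return anchor, regex


def _degron_flags(seq: str, motif: str) -> dict:
    anchor, regex = _motif_to_regex(motif)
    n_win = seq[:TERMINAL_WINDOW]
    c_win = seq[-TERMINAL_WINDOW:]
    safe = re.sub(r"\W", "_", motif)
    if anchor == "n":
        return {f"degron_{safe}_nterm": int(bool(re.match(regex, seq)))}
    if anchor == "c":
        return {f"degron_{safe}_cterm": int(bool(re.search(regex + r"\Z", seq)))}
    return {f"degron_{safe}_nterm": int(bool(re.search(regex, n_win))),
            f"degron_{safe}_cterm": int(bool(re.search(regex, c_win)))}


def compute_sequence_features(sequences, degron_motifs: list | None = None,
                              met_removal: bool = True,
                              ambiguous: str = "skip") -> tuple[pd.DataFrame, list]:
    """Featurize protein sequences.

    Parameters
    ----------
    sequences:
        Path to a FASTA file, or an iterable of ``(protein_id, sequence)``
        pairs / Bio.SeqRecord objects.
    degron_motifs:
        Degron motif strings (see module docstring for the pattern
        language).
    met_removal:
        If True (default), the reported N-terminal residue of sequences
        starting with Met is the penultimate residue, mirroring
        methionine aminopeptidase processing.
    ambiguous:
        ``"skip"`` drops records with non-canonical residues (reported),
        ``"strip"`` removes the offending residues before featurizing.

    Returns
    -------
    (features, skipped):
        Feature table indexed by protein id, and the list of skipped
        record ids.
    """
    if ambiguous not in {"skip", "strip"}:
        raise ConfigError(f"unknown ambiguous policy {ambiguous!r}")
    degron_motifs = list(degron_motifs or [])
    records = []
    if isinstance(sequences, (str, Path)):
        for rec in SeqIO.parse(str(sequences), "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    else:
        for item in sequences:
            if hasattr(item, "id") and hasattr(item, "seq"):
                records.append((item.id, str(item.seq).upper()))
            else:
                pid, seq = item
                records.append((pid, str(seq).upper()))

    rows, skipped = [], []
    seen = set()
    for pid, seq in records:
        if pid in seen:
            raise InputError(f"duplicate protein id in sequences: {pid!r}")
        seen.add(pid)
        bad = set(seq) - set(AMINO_ACIDS)
        if bad or not seq:
            if ambiguous == "strip" and seq:
                seq = "".join(ch for ch in seq if ch in AMINO_ACIDS)
                if not seq:
                    skipped.append(pid)
                    continue
            else:
                skipped.append(pid)
                continue
        pa = ProteinAnalysis(seq)
        comp = {aa: pct / 100.0 for aa, pct in pa.amino_acids_percent.items()}
        row = {
            "protein_id": pid,
            "length": len(seq),
            "mol_weight": pa.molecular_weight(),
            "isoelectric_point": pa.isoelectric_point(),
            "gravy": pa.gravy(),
            "aromaticity": pa.aromaticity(),
        }
        for aa in AMINO_ACIDS:
            row[f"frac_{aa}"] = comp.get(aa, 0.0)
        nterm = seq[1] if (met_removal and seq[0] == "M" and len(seq) > 1) else seq[0]
        cterm = seq[-1]
        for aa in AMINO_ACIDS:
            row[f"nterm_{aa}"] = int(nterm == aa)
            row[f"cterm_{aa}"] = int(cterm == aa)
        for motif in degron_motifs:
            row.update(_degron_flags(seq, motif))
        rows.append(row)

    features = pd.DataFrame(rows)
    if len(features):
        features = features.set_index("protein_id")
    features.attrs["provenance"] = {c: ("degron" if c.startswith("degron_")
                                        else "sequence_derived")
                                    for c in features.columns}
    return features, skipped


def assemble_features(core: pd.DataFrame, external_tables: list | None = None,
                      reduced: bool = False,
                      drop_constant: bool = True) -> tuple[pd.DataFrame, dict]:
    """Left-join external feature tables onto the sequence core.

    Each external table must be indexed (or keyed by a ``protein_id``
    column) without duplicates.  Missing external values stay missing
    and every external column gains a ``<col>__missing`` indicator.
    Column-name collisions across tables are suffixed ``__t<k>``.
    ``reduced=True`` skips external tables entirely.  Constant columns
    are dropped and reported.

    Returns the assembled table and a report dict (provenance per
    column, dropped constants, renamed collisions).
    """
    provenance = dict(core.attrs.get("provenance",
                                     {c: "sequence_derived" for c in core.columns}))
    out = core.copy()
    renamed, external_tables = [], list(external_tables or [])
    if not reduced:
        for k, table in enumerate(external_tables, start=1):
            tbl = table.copy()
            if "protein_id" in tbl.columns:
                tbl = tbl.set_index("protein_id")
            if tbl.index.duplicated().any():
                dup = tbl.index[tbl.index.duplicated()].tolist()
                raise InputError(f"external table {k} has duplicate keys: {dup[:5]}")
            rename = {}
            for col in tbl.columns:
                if col in out.columns:
                    rename[col] = f"{col}__t{k}"
            if rename:
                tbl = tbl.rename(columns=rename)
                renamed.extend(rename.values())
            joined = tbl.reindex(out.index)
            for col in joined.columns:
                out[col] = joined[col]
                out[f"{col}__missing"] = joined[col].isna().astype(int)
                provenance[col] = "external"
                provenance[f"{col}__missing"] = "external"

    dropped = []
    if drop_constant:
        for col in list(out.columns):
            # NaN counts as a distinct value: a half-covered external
            # column is informative even if its observed values coincide
            if out[col].nunique(dropna=False) <= 1:
                dropped.append(col)
                out = out.drop(columns=col)
                provenance.pop(col, None)
    out.attrs["provenance"] = provenance
    report = {"provenance": provenance, "dropped_constant": dropped,
              "renamed_collisions": renamed, "n_external_tables": len(external_tables)}
    return out, report


def read_degron_list(path) -> list:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
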