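"""Harvest candidate protease-substrate annotations from a document corpus.

The mining rule is deliberately simple and deterministic: a sentence is a
candidate iff it contains at least one whole-token gene-symbol match AND
at least one degradation-term match (case-insensitive prefix stemming,
so "degrad" hits "degraded" and "degradation").  Candidates are meant to
be reviewed; :func:`merge_catalog` folds approved candidates together
with a manually curated substrate list into an :class:`AnnotationCatalog`.

The sentence tokenizer is rule based (terminal punctuation plus an
abbreviation exception list) so that results never depend on a trained
model.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigError, InputError
from .simulate import Document

#: Abbreviations whose trailing period must not end a sentence.
DEFAULT_ABBREVIATIONS = (
    "E. coli", "i.e.", "e.g.", "et al.", "cf.", "ca.", "vs.",
    "spp.", "sp.", "Fig.", "approx.",
)

_PLACEHOLDER = "\x00"


def tokenize_sentences(text: str, abbreviations: tuple = DEFAULT_ABBREVIATIONS
                       ) -> list[str]:
    """Split ``text`` into sentences on terminal punctuation.

    Periods inside abbreviations from the exception list never split.
    Joining the returned sentences with single spaces reconstructs the
    text up to whitespace.
    """
    if not text or not text.strip():
        raise InputError("cannot tokenize empty text")
    protected = text
    for abbr in sorted(abbreviations, key=len, reverse=True):
        protected = protected.replace(abbr, abbr.replace(".", _PLACEHOLDER))
    parts = re.split(r"(?<=[.!?])\s+", protected)
    sentences = [p.replace(_PLACEHOLDER, ".").strip() for p in parts if p.strip()]
    return sentences


@dataclass
class CandidateSentence:
    """A sentence matching both a gene symbol and a degradation term."""

    doc_id: str
    sentence_index: int
    sentence: str
    matched_genes: list = field(default_factory=list)
    matched_terms: list = field(default_factory=list)
    protein_ids: list = field(default_factory=list)


def _normalize_alias(alias: str, case_policy: str) -> str:
    if case_policy == "exact":
        return alias
    if case_policy == "first-letter":
        # bacterial symbols: pdeH and PdeH denote the same gene/protein
        return alias[:1].lower() + alias[1:]
    if case_policy == "insensitive":
        return alias.lower()
    raise ConfigError(f"unknown case_policy: {case_policy!r}")


def build_gene_lookup(gene_dict: dict, case_policy: str = "first-letter") -> dict:
    """Map normalized aliases to (alias, protein_id), rejecting collisions."""
    lookup: dict[str, tuple[str, str]] = {}
    for alias, pid in gene_dict.items():
        key = _normalize_alias(alias, case_policy)
        if key in lookup and lookup[key][1] != pid:
            raise ConfigError(
                f"gene alias {alias!r} maps to both {lookup[key][1]!r} and {pid!r}")
        lookup[key] = (alias, pid)
    return lookup


def mine_candidates(corpus: list[Document], gene_dict: dict, terms: list,
                    case_policy: str = "first-letter",
                    term_mode: str = "stem",
                    abbreviations: tuple = DEFAULT_ABBREVIATIONS
                    ) -> list[CandidateSentence]:
    """Return every sentence containing a gene symbol and a degradation term.

    Parameters
    ----------
    corpus:
        Documents to scan.
    gene_dict:
        alias -> protein id.  Whole-token matching; the ``case_policy``
        (``"exact"``, ``"first-letter"`` (default), ``"insensitive"``)
        controls which capitalization variants of an alias are accepted.
    terms:
        Degradation query terms; ``term_mode="stem"`` (default) matches any
        word token whose lowercase form starts with the term, ``"exact"``
        requires token equality.
    """
    if not gene_dict:
        raise ConfigError("gene dictionary is empty")
    if not terms:
        raise ConfigError("term list is empty")
    if term_mode not in {"stem", "exact"}:
        raise ConfigError(f"unknown term_mode: {term_mode!r}")
    lookup = build_gene_lookup(gene_dict, case_policy)
    terms_low = [t.lower() for t in terms]

    candidates: list[CandidateSentence] = []
    for doc in corpus:
        for idx, sentence in enumerate(tokenize_sentences(doc.text, abbreviations)):
            tokens = re.findall(r"[A-Za-z0-9_-]+", sentence)
            hit_genes, hit_pids = [], []
            for tok in tokens:
                key = _normalize_alias(tok, case_policy)
                if key in lookup:
                    alias, pid = lookup[key]
                    if alias not in hit_genes:
                        hit_genes.append(alias)
                        hit_pids.append(pid)
            hit_terms = []
            for term in terms_low:
                ok = any(
                    (tok.lower().startswith(term) if term_mode == "stem"
                     else tok.lower() == term)
                    for tok in tokens)
                if ok:
                    hit_terms.append(term)
            if hit_genes and hit_terms:
                candidates.append(CandidateSentence(
                    doc_id=doc.doc_id, sentence_index=idx, sentence=sentence,
                    matched_genes=hit_genes, matched_terms=hit_terms,
                    protein_ids=hit_pids))
    return candidates


# --------------------------------------------------------------------------
# catalog assembly
# --------------------------------------------------------------------------

VALID_STATUSES = ("curated", "mined_approved", "mined_pending", "rejected")
ANNOTATED_STATUSES = ("curated", "mined_approved")


@dataclass
class AnnotationCatalog:
    """Per-protein substrate annotations with provenance and status."""

    entries: pd.DataFrame          # protein_id, gene_name, status, evidence
    expansion_fraction: float | None = None

    def annotated_ids(self, statuses: tuple = ANNOTATED_STATUSES) -> set:
        mask = self.entries["status"].isin(statuses)
        return set(self.entries.loc[mask, "protein_id"])

    def counts(self) -> dict:
        c = self.entries["status"].value_counts().to_dict()
        c["annotated"] = int(self.entries["status"].isin(ANNOTATED_STATUSES).sum())
        return c

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "counts": self.counts(),
            "expansion_fraction": self.expansion_fraction,
            "entries": self.entries.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def candidates_to_table(candidates: list[CandidateSentence]) -> pd.DataFrame:
    """Review-table export: one row per (candidate sentence, gene)."""
    rows = []
    for c in candidates:
        for gene, pid in zip(c.matched_genes, c.protein_ids):
            rows.append({
                "doc_id": c.doc_id, "sentence_index": c.sentence_index,
                "gene": gene, "protein_id": pid,
                "matched_terms": ";".join(c.matched_terms),
                "sentence": c.sentence, "decision": "",
            })
    return pd.DataFrame(rows, columns=["doc_id", "sentence_index", "gene",
                                       "protein_id", "matched_terms",
                                       "sentence", "decision"])


def merge_catalog(curated: pd.DataFrame, mined: list[CandidateSentence],
                  decisions: pd.DataFrame | None = None) -> AnnotationCatalog:
    """Fold curated annotations and (optionally reviewed) candidates together.

    ``curated`` needs columns ``protein_id`` and ``gene_name`` (optional
    ``evidence``).  ``decisions`` is a review table with columns
    ``doc_id``, ``sentence_index``, ``gene`` and ``decision``
    (``approve``/``reject``); undecided candidates stay ``mined_pending``.
    Curated status always wins on a shared protein.  The expansion
    fraction is |approved mined proteins not already curated| / |curated|.
    """
    for col in ("protein_id", "gene_name"):
        if col not in curated.columns:
            raise InputError(f"curated table missing column {col!r}")
    if curated["protein_id"].duplicated().any():
        raise InputError("curated table has duplicate protein ids")

    known = {(c.doc_id, c.sentence_index, g) for c in mined for g in c.matched_genes}
    decided: dict[tuple, str] = {}
    if decisions is not None and len(decisions):
        for _, row in decisions.iterrows():
            key = (row["doc_id"], int(row["sentence_index"]), row["gene"])
            if key not in known:
                raise InputError(f"decision refers to unknown candidate {key}")
            verdict = str(row["decision"]).strip().lower()
            if verdict not in {"approve", "reject", ""}:
                raise InputError(f"unknown decision {row['decision']!r} for {key}")
            if verdict:
                decided[key] = verdict

    rows = []
    for _, row in curated.iterrows():
        rows.append({"protein_id": row["protein_id"], "gene_name": row["gene_name"],
                     "status": "curated",
                     "evidence": str(row.get("evidence", "manual curation"))})
    catalog = {r["protein_id"]: r for r in rows}

    approved_novel = set()
    for c in mined:
        for gene, pid in zip(c.matched_genes, c.protein_ids):
            verdict = decided.get((c.doc_id, c.sentence_index, gene))
            status = {"approve": "mined_approved", "reject": "rejected",
                      None: "mined_pending"}[verdict]
            evidence = f"{c.doc_id}#{c.sentence_index}: {c.sentence}"
            if pid in catalog:
                prev = catalog[pid]
                if prev["status"] == "curated":
                    prev["evidence"] += f" | {evidence}"
                    continue
                rank = {"mined_approved": 2, "mined_pending": 1, "rejected": 0}
                if rank[status] > rank[prev["status"]]:
                    prev["status"] = status
                prev["evidence"] += f" | {evidence}"
            else:
                catalog[pid] = {"protein_id": pid, "gene_name": gene,
                                "status": status, "evidence": evidence}
            if status == "mined_approved" and \
                    pid not in set(curated["protein_id"]):
                approved_novel.add(pid)

    entries = pd.DataFrame(list(catalog.values()),
                           columns=["protein_id", "gene_name", "status", "evidence"])
    expansion = len(approved_novel) / len(curated) if len(curated) else None
    return AnnotationCatalog(entries=entries, expansion_fraction=expansion)


# --------------------------------------------------------------------------
# dictionary / term file formats (one entry per line; tab-separated aliases)
# --------------------------------------------------------------------------

def read_gene_dict(path) -> dict:
    """Lines of ``protein_id<TAB>alias1<TAB>alias2...`` -> alias->id map."""
    gene_dict: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        pid, aliases = fields[0], fields[1:]
        if not aliases:
            raise InputError(f"gene dictionary line lacks aliases: {line!r}")
        for alias in aliases:
            if alias in gene_dict and gene_dict[alias] != pid:
                raise ConfigError(
                    f"alias {alias!r} maps to both {gene_dict[alias]!r} and {pid!r}")
            gene_dict[alias] = pid
    return gene_dict


def read_term_list(path) -> list:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
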