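"""Synthetic inputs with known ground truth.

Three generators stand in for the wet-lab and literature inputs of the
turnover pipeline:

* :func:`simulate_decay_matrix` — protein-level TMT pulse-chase traces.
  Each protein starts at an initial abundance ``A0`` drawn log-uniformly
  over several decades.  A minority of proteins decays exponentially,
  ``A(t) = A0 * 2**(-t / t_half)``, with half-lives drawn log-uniformly;
  the stable majority has ``t_half = inf``.  Noise is multiplicative
  lognormal (Gaussian on the log2 scale), each channel carries an
  additive log2 offset shared by all proteins (the distortion cyclic
  loess is meant to remove), and missing values land preferentially on
  the lowest intensities, as in real isobaric-label data.

* :func:`simulate_corpus` — a document corpus with planted
  "gene + degradation term" sentences and distractors, for the
  annotation-mining stage.

* :func:`simulate_feature_label_set` — a feature table and binary
  instability labels with controllable prevalence and class separation,
  for the classifier.

All generators are deterministic given their spec's ``seed``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix
from .errors import ConfigError

DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 4.0)
STATIONARY_TIMEPOINTS = (0.0, 1.0, 2.0, 4.0, 8.0)


def round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1).

    Used wherever a fractional design quantity (expected positive count,
    expected missing cells) becomes an integer, so that realized counts
    are reproducible and documented.
    """
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


# --------------------------------------------------------------------------
# decay traces
# --------------------------------------------------------------------------

@dataclass
class DecaySimSpec:
    """Design of a simulated pulse-chase TMT experiment."""

    n_proteins: int = 1000
    frac_unstable: float = 0.1
    timepoints: tuple = DEFAULT_TIMEPOINTS
    replicates_per_timepoint: int = 2
    halflife_range_unstable: tuple = (0.5, 8.0)
    log10_abundance_range: tuple = (4.0, 8.0)
    noise_sd: float = 0.1
    channel_bias_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not 0.0 <= self.frac_unstable <= 1.0:
            raise ConfigError("frac_unstable must lie in [0, 1]")
        tp = tuple(float(t) for t in self.timepoints)
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError("timepoints must be strictly increasing with >= 2 entries")
        if tp[0] != 0.0:
            raise ConfigError("timepoints must start at 0")
        self.timepoints = tp
        if self.replicates_per_timepoint < 1:
            raise ConfigError("replicates_per_timepoint must be >= 1")
        lo, hi = self.halflife_range_unstable
        if not (0 < lo < hi):
            raise ConfigError("halflife_range_unstable requires 0 < low < high")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.channel_bias_sd < 0:
            raise ConfigError("channel_bias_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")


def simulate_decay_matrix(spec: DecaySimSpec,
                          truth: pd.DataFrame | None = None
                          ) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Simulate an :class:`AbundanceMatrix` and its ground-truth table.

    Parameters
    ----------
    spec:
        Simulation design.
    truth:
        Optional truth table from a previous call (columns ``protein_id``,
        ``is_unstable``, ``true_halflife``, ``true_A0``).  When given, the
        same proteins and kinetic parameters are reused and only the
        observation design and noise are redrawn — this is how a second
        growth phase sharing substrates with the first is simulated.

    Returns
    -------
    (matrix, truth):
        ``truth`` has one row per protein with ``true_halflife = inf``
        for stable proteins.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins

    if truth is None:
        protein_ids = [f"P{i:05d}" for i in range(n)]
        n_unstable = round_half_away(spec.frac_unstable * n)
        is_unstable = np.zeros(n, dtype=bool)
        unstable_idx = rng.choice(n, size=n_unstable, replace=False)
        is_unstable[unstable_idx] = True
        lo, hi = spec.halflife_range_unstable
        halflife = np.full(n, np.inf)
        halflife[is_unstable] = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=n_unstable))
        a_lo, a_hi = spec.log10_abundance_range
        a0 = 10.0 ** rng.uniform(a_lo, a_hi, size=n)
        truth = pd.DataFrame({
            "protein_id": protein_ids,
            "is_unstable": is_unstable,
            "true_halflife": halflife,
            "true_A0": a0,
        })
    else:
        truth = truth.reset_index(drop=True).copy()
        protein_ids = truth["protein_id"].tolist()
        halflife = truth["true_halflife"].to_numpy(dtype=float)
        a0 = truth["true_A0"].to_numpy(dtype=float)
        n = len(truth)

    channels, times = [], []
    for ti, t in enumerate(spec.timepoints):
        for r in range(spec.replicates_per_timepoint):
            channels.append(f"C{ti * spec.replicates_per_timepoint + r + 1:02d}")
            times.append((t, r + 1))
    design = pd.DataFrame({
        "channel": channels,
        "time_h": [t for t, _ in times],
        "replicate": [r for _, r in times],
    })

    t_vec = np.array([t for t, _ in times])
    # log2 A(t) = log2 A0 - t / t_half  (+ channel bias + noise)
    with np.errstate(divide="ignore"):
        decay = np.where(np.isfinite(halflife)[:, None],
                         -t_vec[None, :] / halflife[:, None], 0.0)
    log2_signal = np.log2(a0)[:, None] + decay
    bias = rng.normal(0.0, spec.channel_bias_sd, size=len(channels)) \
        if spec.channel_bias_sd > 0 else np.zeros(len(channels))
    noise = rng.normal(0.0, spec.noise_sd, size=(n, len(channels))) \
        if spec.noise_sd > 0 else 0.0
    intensities = 2.0 ** (log2_signal + bias[None, :] + noise)

    if spec.missing_rate > 0:
        flat = intensities.ravel()
        n_missing = round_half_away(spec.missing_rate * flat.size)
        if n_missing > 0:
            # low-intensity cells drop out preferentially
            weights = 1.0 / flat
            weights /= weights.sum()
            drop = rng.choice(flat.size, size=n_missing, replace=False, p=weights)
            flat = flat.copy()
            flat[drop] = np.nan
            intensities = flat.reshape(intensities.shape)

    data = pd.DataFrame(intensities, index=pd.Index(protein_ids, name="protein_id"),
                        columns=channels)
    return AbundanceMatrix(data=data, design=design), truth


# --------------------------------------------------------------------------
# annotation corpora
# --------------------------------------------------------------------------

@dataclass
class CorpusSimSpec:
    """Design of a planted document corpus for annotation mining."""

    gene_names: tuple
    degradation_terms: tuple
    n_documents: int = 50
    n_planted_positive: int = 10
    distractor_gene_frac: float = 0.5   # of non-planted docs, share that get a gene-only sentence
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_names = tuple(self.gene_names)
        self.degradation_terms = tuple(self.degradation_terms)
        if not self.gene_names:
            raise ConfigError("gene_names must be nonempty")
        if not self.degradation_terms:
            raise ConfigError("degradation_terms must be nonempty")
        if self.n_planted_positive > self.n_documents:
            raise ConfigError("n_planted_positive must be <= n_documents")
        if not 0.0 <= self.distractor_gene_frac <= 1.0:
            raise ConfigError("distractor_gene_frac must lie in [0, 1]")


@dataclass
class Document:
    doc_id: str
    source: str
    text: str


_NEUTRAL_SENTENCES = (
    "Bacterial physiology adapts to nutrient availability.",
    "Growth conditions were monitored throughout the experiment.",
    "Cellular fitness depends on balanced resource allocation.",
)
_GENE_TEMPLATES = (
    "{gene} localizes to the cytoplasm under these conditions.",
    "Expression of {gene} rises during entry into quiescence.",
)
_TERM_TEMPLATES = (
    "Misfolded polypeptides can be {term} under heat stress.",
    "Many substrates are {term} only in specific growth states.",
)
_POSITIVE_TEMPLATE = "{gene} is rapidly {term} by an ATP-dependent protease."


def _contains_term(sentence: str, terms: tuple) -> bool:
    low = sentence.lower()
    return any(tok.startswith(term.lower())
               for tok in re.findall(r"[a-z0-9]+", low)
               for term in terms)


def _contains_gene(sentence: str, genes: tuple) -> bool:
    toks = set(re.findall(r"[A-Za-z0-9_-]+", sentence))
    toks |= {t.lower() for t in toks}
    return any(g in toks or g.lower() in toks for g in genes)


def simulate_corpus(spec: CorpusSimSpec) -> tuple[list[Document], pd.DataFrame]:
    """Build a corpus with exactly ``n_planted_positive`` positive documents.

    Each planted document carries one sentence pairing a gene name with a
    degradation term; distractor documents carry at most one of the two
    (a gene without any term, a term without any gene, or neither).  The
    returned truth table lists the planted (doc_id, sentence_index, gene)
    triples.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names
    terms = spec.degradation_terms

    # templates must not accidentally contain a query term / gene name
    neutral = [s for s in _NEUTRAL_SENTENCES if not _contains_term(s, terms)
               and not _contains_gene(s, genes)]
    gene_templates = [t for t in _GENE_TEMPLATES
                      if not _contains_term(t.format(gene=""), terms)]
    term_templates = [t for t in _TERM_TEMPLATES
                      if not _contains_gene(t.format(term=""), genes)]
    if not neutral or not gene_templates or not term_templates:
        raise ConfigError("gene/term dictionaries collide with every distractor template")

    docs: list[Document] = []
    truth_rows = []
    planted_flags = np.zeros(spec.n_documents, dtype=bool)
    if spec.n_planted_positive:
        planted_flags[rng.choice(spec.n_documents, size=spec.n_planted_positive,
                                 replace=False)] = True

    for i in range(spec.n_documents):
        doc_id = f"DOC{i:04d}"
        source = "abstract" if i % 2 == 0 else "gene_summary"
        opener = neutral[int(rng.integers(len(neutral)))]
        if planted_flags[i]:
            gene = genes[int(rng.integers(len(genes)))]
            term = terms[int(rng.integers(len(terms)))]
            planted = _POSITIVE_TEMPLATE.format(gene=gene, term=term)
            closer = neutral[int(rng.integers(len(neutral)))]
            sentences = [opener, planted, closer]
            truth_rows.append({"doc_id": doc_id, "sentence_index": 1, "gene": gene})
        else:
            if rng.random() < spec.distractor_gene_frac:
                gene = genes[int(rng.integers(len(genes)))]
                tmpl = gene_templates[int(rng.integers(len(gene_templates)))]
                sentences = [opener, tmpl.format(gene=gene)]
            else:
                term = terms[int(rng.integers(len(terms)))]
                tmpl = term_templates[int(rng.integers(len(term_templates)))]
                sentences = [opener, tmpl.format(term=term)]
        docs.append(Document(doc_id=doc_id, source=source, text=" ".join(sentences)))

    truth = pd.DataFrame(truth_rows, columns=["doc_id", "sentence_index", "gene"])
    return docs, truth


# --------------------------------------------------------------------------
# classifier feature/label sets
# --------------------------------------------------------------------------

@dataclass
class FeatureSimSpec:
    """Design of a synthetic feature table + instability labels."""

    n_examples: int = 2041
    prevalence: float = 262 / 2041
    n_features: int = 20
    n_informative: int = 10
    effect_size: float = 1.0        # class-mean shift in within-class SDs
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_examples < 2:
            raise ConfigError("n_examples must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError("prevalence must lie in (0, 1)")
        if self.n_informative > self.n_features:
            raise ConfigError("n_informative must be <= n_features")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if round_half_away(self.prevalence * self.n_examples) == 0:
            raise ConfigError("prevalence yields zero positive examples")


def simulate_feature_label_set(spec: FeatureSimSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian features with a planted class-mean shift.

    The realized positive count is ``round(prevalence * n_examples)``
    (half away from zero).  Informative features differ between classes
    by ``effect_size`` within-class standard deviations; the remaining
    features are identically distributed in both classes.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_examples, spec.n_features
    n_pos = round_half_away(spec.prevalence * n)

    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_pos, replace=False)] = 1

    X = rng.normal(0.0, 1.0, size=(n, p))
    X[:, :spec.n_informative] += spec.effect_size * y[:, None]

    if spec.missing_rate > 0:
        mask = rng.random(size=(n, p)) < spec.missing_rate
        X = np.where(mask, np.nan, X)

    ids = pd.Index([f"E{i:05d}" for i in range(n)], name="protein_id")
    cols = [f"f{j:03d}" for j in range(p)]
    features = pd.DataFrame(X, index=ids, columns=cols)
    features.attrs["informative"] = cols[:spec.n_informative]
    labels = pd.Series(y, index=ids, name="is_unstable")
    return features, labels


# --------------------------------------------------------------------------
# JSONL / TSV helpers
# --------------------------------------------------------------------------

def write_corpus_jsonl(docs: list[Document], path) -> None:
    import json
    with open(path, "w") as fh:
        for d in docs:
            fh.write(json.dumps({"id": d.doc_id, "source": d.source, "text": d.text}))
            fh.write("\n")


def read_corpus_jsonl(path) -> list[Document]:
    import json
    docs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            docs.append(Document(doc_id=rec["id"], source=rec.get("source", "other"),
                                 text=rec["text"]))
    return docs
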