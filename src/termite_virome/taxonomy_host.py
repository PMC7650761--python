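"""Species delimitation, rule-based host inference and clade summaries.

Viruses whose replicase proteins share more than 95% amino-acid identity
are one species; identity comes from a global alignment with
BLOSUM62-valued substitution scores and a linear gap penalty, counting
matches over aligned columns excluding terminal gaps.

Host inference encodes the study's narrative reasoning as an ordered,
data-driven rule list: phage-family clades point to bacteria, mitovirus
clades with fungal relatives to the fungal community, plant-associated
relatives at modest abundance to the diet, low-abundance dsRNA viruses
confined to whole-body (gut-containing) libraries to symbionts, and
high-abundance viruses with arthropod-associated relatives to the
termite itself — with confidence raised when a detection comes from a
head-only library, where gut symbionts are excluded.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import yaml
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

SPECIES_IDENTITY_THRESHOLD = 95.0

HOST_CATEGORIES = (
    "Termite", "Symbiont", "Bacteria", "Fungus-associated",
    "Plant", "Diet", "No inference",
)

_ABUNDANCE_ORDER = {"low": 0, "moderate": 1, "high": 2}
_CONFIDENCE_ORDER = {"none": 0, "cautious": 1, "suggested": 2}


@dataclass(frozen=True)
class HostPrediction:
    category: str
    evidence: tuple
    confidence: str

    def __post_init__(self):
        if self.category not in HOST_CATEGORIES:
            raise ValueError(f"unknown host category {self.category!r}")
        if self.confidence not in _CONFIDENCE_ORDER:
            raise ValueError(f"unknown confidence {self.confidence!r}")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -4.0  # linear gap penalty
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(protein_a: str, protein_b: str) -> float:
    """Percent identity from a global BLOSUM62 alignment.

    Identity = matches / aligned columns, where terminal-gap columns are
    excluded and internal-gap columns count as aligned (mismatching)
    columns.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    alignment = _ALIGNER.align(protein_a.upper(), protein_b.upper())[0]
    s1, s2 = str(alignment[0]), str(alignment[1])
    lo, hi = 0, len(s1)
    while lo < hi and (s1[lo] == "-" or s2[lo] == "-"):
        lo += 1
    while hi > lo and (s1[hi - 1] == "-" or s2[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    matches = sum(1 for a, b in zip(s1[lo:hi], s2[lo:hi]) if a == b and a != "-")
    return 100.0 * matches / (hi - lo)


def identity_matrix(proteins: dict) -> pd.DataFrame:
    """All-vs-all percent identity for named replicase proteins."""
    names = list(proteins)
    m = np.full((len(names), len(names)), 100.0)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            ident = pairwise_identity(proteins[a], proteins[names[j]])
            m[i, j] = m[j, i] = ident
    return pd.DataFrame(m, index=names, columns=names)


def cluster_species(
    identity: pd.DataFrame, threshold: float = SPECIES_IDENTITY_THRESHOLD
) -> dict:
    """Single-linkage species clusters: connected components of the graph
    with an edge wherever identity is strictly above the threshold.

    Returns a name → cluster-id map; ids are dense and ordered by first
    appearance.
    """
    values = identity.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("identity matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("identity matrix must be symmetric")
    if not np.allclose(np.diag(values), 100.0):
        raise ValueError("identity matrix diagonal must be 100")
    adj = csr_matrix(values > threshold)
    _, labels = connected_components(adj, directed=False)
    remap: dict[int, int] = {}
    out = {}
    for name, lab in zip(identity.index, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[str(name)] = remap[lab]
    return out


# ---------------------------------------------------------------------------
# host-inference rule engine

#: The default, ordered rule list.  Each rule is a condition set over the
#: evaluation context; the first rule whose every condition holds fires.
DEFAULT_HOST_RULES = [
    {
        "name": "phage-family",
        "clade_in": ["Leviviridae"],
        "category": "Bacteria",
        "confidence": "suggested",
    },
    {
        "name": "mitovirus-fungal",
        "clade_in": ["Mitovirus", "Mitovirus-like", "Mitovirus(-like)"],
        "relative_host_in": ["fungi", "fungus"],
        "category": "Fungus-associated",
        "confidence": "suggested",
    },
    {
        "name": "plant-diet",
        "relative_host_in": ["plant"],
        "max_abundance_at_most": "moderate",
        "category": "Plant",
        "confidence": "suggested",
    },
    {
        "name": "gut-symbiont",
        "group_in": ["Partiti-Picobirna"],
        "max_abundance_is": "low",
        "all_whole_body": True,
        "category": "Symbiont",
        "confidence": "suggested",
    },
    {
        "name": "termite-infecting",
        "relative_host_in": ["arthropod"],
        "max_abundance_is": "high",
        "category": "Termite",
        "confidence": "cautious",
        "raise_confidence_if_head_only": True,
    },
    {
        "name": "no-inference",
        "category": "No inference",
        "confidence": "none",
    },
]


def load_rules(path) -> list:
    """Load an ordered host-rule list from a YAML file."""
    with open(path) as fh:
        rules = yaml.safe_load(fh)
    if not isinstance(rules, list):
        raise ValueError("rule file must contain a list of rules")
    return rules


def _norm(s: str) -> str:
    return s.replace("–", "-").strip().lower()


def _rule_matches(rule: dict, ctx: dict) -> bool:
    if "clade_in" in rule and ctx["clade"] not in {_norm(c) for c in rule["clade_in"]}:
        return False
    if "group_in" in rule and ctx["group"] not in {_norm(g) for g in rule["group_in"]}:
        return False
    if "relative_host_in" in rule and ctx["relative_host"] not in {
        _norm(h) for h in rule["relative_host_in"]
    }:
        return False
    if "max_abundance_is" in rule and ctx["max_abundance"] != rule["max_abundance_is"]:
        return False
    if "max_abundance_at_most" in rule and (
        _ABUNDANCE_ORDER[ctx["max_abundance"]]
        > _ABUNDANCE_ORDER[rule["max_abundance_at_most"]]
    ):
        return False
    if rule.get("all_whole_body") and not ctx["all_whole_body"]:
        return False
    return True


KNOWN_CLADES = frozenset(
    _norm(c)
    for c in (
        "Idaeovirus-like", "Negev-like", "Sobemo-like", "Iflaviridae",
        "Polycipiviridae", "Nora-like", "Kelp fly virus related",
        "Flaviviridae", "Mitovirus", "Mitovirus-like", "Mitovirus(-like)",
        "Narna-like", "Leviviridae", "Lispi-like", "Bunya-like",
        "Phasmavirus", "Picobirnaviridae", "Picobirna-like A",
        "Picobirna-like B", "Amalga-like", "Partiti-like A",
        "Partiti-like B", "unassigned",
    )
)


def infer_host(record, detections, library_meta, rules=None) -> HostPrediction:
    """Apply the ordered host rules to one curated virus.

    ``detections`` are the virus's per-library observations (with
    abundance classes); ``library_meta`` maps library_id to its metadata
    (for the whole-body / head-only procedure).  The first matching rule
    fires; an unrecognized clade label yields 'No inference' with a
    warning.
    """
    rules = DEFAULT_HOST_RULES if rules is None else rules
    clade = _norm(record.clade)
    if clade not in KNOWN_CLADES:
        warnings.warn(f"unknown clade label {record.clade!r}; no host inference")
        return HostPrediction("No inference", ("unknown-clade",), "none")
    mine = [d for d in detections if d.virus_name == record.virus_name]
    if mine:
        max_ab = max(mine, key=lambda d: _ABUNDANCE_ORDER[d.abundance_class]).abundance_class
    else:
        max_ab = "low"
    procedures = {library_meta[d.library_id].procedure for d in mine}
    ctx = {
        "clade": clade,
        "group": _norm(record.group),
        "relative_host": _norm(
            record.closest_relative.host_category if record.closest_relative else ""
        ),
        "max_abundance": max_ab,
        "all_whole_body": bool(mine) and procedures == {"whole-body"},
        "any_head_only": "head-only" in procedures,
    }
    for rule in rules:
        if _rule_matches(rule, ctx):
            confidence = rule["confidence"]
            evidence = [rule["name"]]
            if rule.get("raise_confidence_if_head_only") and ctx["any_head_only"]:
                confidence = "suggested"
                evidence.append("head-only-detection")
            return HostPrediction(rule["category"], tuple(evidence), confidence)
    return HostPrediction("No inference", (), "none")


# ---------------------------------------------------------------------------
# clade summaries

def round_sig_half_up(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, halves away from zero."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    q = Decimal(1).scaleb(d.adjusted() - sig + 1)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def round_decimal_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CladeSummary:
    clade: str
    group: str
    n_novel_viruses: int
    host_prediction: str
    mean_abundance: float  # % of total reads, 2 significant figures
    mean_identity: float  # % aa to closest relative, 1 decimal


def summarize_clades(records, detections, host_predictions=None) -> list[CladeSummary]:
    """Per-clade summary of the curated virome.

    Mean abundance averages percent-of-total over the clade's detections
    (virus × library observations, not viruses) and is rounded
    half-away-from-zero to 2 significant figures; mean identity averages
    the per-virus identity to the closest relative, 1 decimal.
    """
    by_clade: dict[str, list] = {}
    for rec in records:
        by_clade.setdefault(rec.clade, []).append(rec)
    det_by_virus: dict[str, list] = {}
    for d in detections:
        det_by_virus.setdefault(d.virus_name, []).append(d)
    summaries = []
    for clade, recs in sorted(by_clade.items()):
        names = [r.virus_name for r in recs]
        clade_dets = [d for n in names for d in det_by_virus.get(n, [])]
        mean_ab = (
            float(np.mean([d.percent_total for d in clade_dets])) if clade_dets else 0.0
        )
        mean_id = float(np.mean([r.percent_identity_to_relative for r in recs]))
        if host_predictions:
            cats = Counter(
                host_predictions[n].category for n in names if n in host_predictions
            )
            host = cats.most_common(1)[0][0] if cats else "No inference"
        else:
            host = "No inference"
        summaries.append(
            CladeSummary(
                clade=clade,
                group=recs[0].group,
                n_novel_viruses=len(recs),
                host_prediction=host,
                mean_abundance=round_sig_half_up(mean_ab, 2),
                mean_identity=round_decimal_half_up(mean_id, 1),
            )
        )
    return summaries
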