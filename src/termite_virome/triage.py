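"""Candidate identification and exclusion rules producing the curated virus table.

A contig becomes a virus candidate when its best hit against a reference
RNA virus is significant (e-value < 1e-5) and no conserved-domain search
hit on it is non-viral.  Candidates are then screened: hits whose closest
relative is a known cross-contaminant (bovine viral diarrhea virus 1,
human picobirnavirus) are flagged, hits to DNA viruses are excluded, and
sequences that lack a complete genome in high abundance while their
replicase homology region is interrupted by frameshifts/premature stops
are flagged as endogenized copies of viruses rather than exogenous
viruses.  Every decision is logged with the rule that triggered it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from termite_virome.io_formats import DomainHit, HomologyHit, ReferenceVirus

DEFAULT_CONTAMINANT_BLACKLIST = frozenset(
    {"bovine viral diarrhea virus 1", "human picobirnavirus"}
)

#: Mono–Chu relatives that repeatedly produced endogenized copies in
#: termite assemblies; a hit to one of these forces the interrupted-ORF
#: check but is never an automatic exclusion.
SUSPECT_ENDOGENOUS_RELATIVES = frozenset(
    {
        "Hubei chuvirus",
        "Hubei chuvirus 4",
        "Hubei oodonate virus 11",
        "Hubei rhabdo-like virus 3",
        "Lampyris noctiluca chuvirus-like virus 1",
        "Wuchan romanomermis nematode virus 3",
        "Hubei orthoptera virus 5",
    }
)

VALID_GROUPS = frozenset(
    {
        "Flaviviridae",
        "Hepe-Virga",
        "Bunya-Arena",
        "Mono-Chu",
        "Luteo-Sobemo",
        "Picorna-Calici",
        "Narna-Levi",
        "Partiti-Picobirna",
        "unassigned",
    }
)


@dataclass(frozen=True)
class TriageThresholds:
    """Tunable cutoffs for candidate retention and exclusion."""

    evalue_max: float = 1e-5
    completeness_min: float = 0.8
    endogenous_orf_coverage: float = 0.9
    contaminant_blacklist: frozenset = DEFAULT_CONTAMINANT_BLACKLIST
    # if True, the high-abundance clause alone (without completeness)
    # rescues an interrupted sequence from the endogenous flag
    rescue_on_abundance_only: bool = False

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        for name in ("completeness_min", "endogenous_orf_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class VirusRecord:
    """A curated virus with its evidence and exclusion flags."""

    virus_name: str
    contig_ids: tuple
    library_ids: tuple
    clade: str
    group: str
    genome_length: int
    closest_relative: ReferenceVirus | None
    percent_identity_to_relative: float
    completeness_ratio: float
    code_id: int = 1
    endogenous: bool = False
    contaminant_blacklist: bool = False
    dna_virus_excluded: bool = False
    index_hop_removed: bool = False

    @property
    def excluded(self) -> bool:
        return self.endogenous or self.contaminant_blacklist or self.dna_virus_excluded


@dataclass(frozen=True)
class TriageDecision:
    contig_id: str
    retained: bool
    rule: str
    detail: str = ""


def filter_candidates(
    hits: list[HomologyHit],
    domains: list[DomainHit],
    thresholds: TriageThresholds = TriageThresholds(),
    contig_ids: list[str] | None = None,
) -> tuple[set[str], list[TriageDecision]]:
    """Retain contigs with a credible viral hit and no non-viral domain.

    A contig is retained iff its best e-value against any viral subject
    is below ``evalue_max`` AND no conserved-domain hit on it is tagged
    non-viral.  Returns the retained set and a per-contig decision log.
    """
    best_evalue: dict[str, float] = {}
    for h in hits:
        prev = best_evalue.get(h.query_id)
        if prev is None or h.evalue < prev:
            best_evalue[h.query_id] = h.evalue
    nonviral_domain: dict[str, DomainHit] = {}
    for d in domains:
        if not d.is_viral and d.query_id not in nonviral_domain:
            nonviral_domain[d.query_id] = d

    universe = list(contig_ids) if contig_ids is not None else sorted(best_evalue)
    retained: set[str] = set()
    log: list[TriageDecision] = []
    for cid in universe:
        ev = best_evalue.get(cid)
        if ev is None:
            log.append(TriageDecision(cid, False, "no-viral-hit"))
        elif ev >= thresholds.evalue_max:
            log.append(
                TriageDecision(
                    cid, False, "evalue-above-threshold",
                    f"best e-value {ev:g} >= {thresholds.evalue_max:g}",
                )
            )
        elif cid in nonviral_domain:
            d = nonviral_domain[cid]
            log.append(
                TriageDecision(
                    cid, False, "non-viral-domain",
                    f"{d.domain_accession} ({d.description})",
                )
            )
        else:
            retained.add(cid)
            log.append(
                TriageDecision(cid, True, "credible-viral-hit", f"best e-value {ev:g}")
            )
    return retained, log


def completeness_ratio(contig_length: int, relative_genome_length: int) -> float:
    """Contig length over the closest relative's genome length (may exceed 1)."""
    if relative_genome_length <= 0:
        raise ValueError("relative genome length must be positive")
    if contig_length <= 0:
        raise ValueError("contig length must be positive")
    return contig_length / relative_genome_length


def flag_endogenous(
    record: VirusRecord,
    interrupted: bool,
    abundance_class: str,
    thresholds: TriageThresholds = TriageThresholds(),
) -> bool:
    """Endogenization rule: an interrupted replicase homology region marks
    the sequence endogenous unless rescued by being (close to) complete
    AND at high abundance — the signature of a genuine exogenous virus.
    """
    if not interrupted:
        return False
    complete = record.completeness_ratio >= thresholds.completeness_min
    high = abundance_class == "high"
    rescued = high if thresholds.rescue_on_abundance_only else (complete and high)
    return not rescued


def apply_exclusions(
    records: list[VirusRecord],
    orf_interrupted: dict,
    abundance_class: dict,
    thresholds: TriageThresholds = TriageThresholds(),
) -> tuple[list[VirusRecord], list[VirusRecord]]:
    """Apply blacklist / DNA-virus / endogenous flags to candidate records.

    ``orf_interrupted`` and ``abundance_class`` are keyed by virus name.
    Records lacking a closest-relative annotation are routed to the
    returned ``unclassifiable`` list rather than silently kept.
    """
    flagged: list[VirusRecord] = []
    unclassifiable: list[VirusRecord] = []
    for rec in records:
        rel = rec.closest_relative
        if rel is None:
            unclassifiable.append(rec)
            continue
        updates: dict = {}
        if rel.name.lower() in {n.lower() for n in thresholds.contaminant_blacklist}:
            updates["contaminant_blacklist"] = True
        if rel.nucleic_acid.upper() == "DNA":
            updates["dna_virus_excluded"] = True
        interrupted = orf_interrupted.get(rec.virus_name, False)
        abclass = abundance_class.get(rec.virus_name, "low")
        if flag_endogenous(rec, interrupted, abclass, thresholds):
            updates["endogenous"] = True
        flagged.append(replace(rec, **updates) if updates else rec)
    return flagged, unclassifiable


def assign_clade_group(
    hits_for_contig: list[HomologyHit],
    reference_annotation: dict,
) -> tuple[str, str, ReferenceVirus]:
    """Inherit clade and group from the best-bitscore hit's reference.

    When several hits disagree the best-bitscore row wins; a relative
    with no clade yields clade 'unassigned'.  Unknown group labels are a
    validation error.
    """
    if not hits_for_contig:
        raise ValueError("no hits supplied")
    annotated = [h for h in hits_for_contig if h.subject_accession in reference_annotation]
    if not annotated:
        raise ValueError("no hit has a reference annotation")
    best = max(annotated, key=lambda h: h.bitscore)
    ref = reference_annotation[best.subject_accession]
    clade = ref.clade if ref.clade else "unassigned"
    # tolerate the typographic en-dash in group labels
    group = (ref.group or "unassigned").replace("–", "-")
    if group not in VALID_GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    return clade, group, ref


_CONSONANTS = "bcdfghjklmnpqrstvwxz"
_VOWELS = "aeiou"


class VirusNamer:
    """Deterministic generator of unique '-systermes virus' names.

    Prefixes are pronounceable 3–4 letter consonant/vowel alternations
    (CVC or CVCV), drawn from a seeded stream; collisions regenerate.
    """

    def __init__(self, rng_seed: int):
        self._rng = np.random.default_rng(rng_seed)
        self._used: set[str] = set()
        # CVC: 20*5*20 = 2000; CVCV: 10000 → namespace of 12000 prefixes
        self._capacity = len(_CONSONANTS) ** 2 * len(_VOWELS) + (
            len(_CONSONANTS) * len(_VOWELS)
        ) ** 2

    def _prefix(self) -> str:
        rng = self._rng
        c = lambda: _CONSONANTS[rng.integers(len(_CONSONANTS))]
        v = lambda: _VOWELS[rng.integers(len(_VOWELS))]
        if rng.random() < 0.5:
            return c() + v() + c()
        return c() + v() + c() + v()

    def next_name(self) -> str:
        if len(self._used) >= self._capacity:
            raise RuntimeError("virus-name namespace exhausted")
        while True:
            prefix = self._prefix()
            if prefix not in self._used:
                self._used.add(prefix)
                return prefix.capitalize() + "systermes virus"


def make_virus_names(n: int, rng_seed: int) -> list[str]:
    namer = VirusNamer(rng_seed)
    return [namer.next_name() for _ in range(n)]
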