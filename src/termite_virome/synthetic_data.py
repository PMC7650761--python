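"""Synthetic virome bundles with ground truth.

Generates internally consistent toy-scale inputs mirroring the structure
of a termite metatranscriptomic survey: per-library metadata (whole-body
vs head-only sampling, country, diet, total reads), assembled contigs
containing planted exogenous viral genomes (a fraction requiring UGA=Trp
variant genetic codes), endogenized copies degraded by frameshifting
indels, non-viral decoy contigs, homology and conserved-domain hit
tables, and a virus × library read-count matrix with planted
cross-library index-hopping events.  Every planted fact is recorded in a
GroundTruth object so recovery by the triage/abundance/host modules can
be scored exactly.

Genomes are random-uniform sequence with planted ORFs; homology e-values
and identities are drawn from configured ranges rather than computed by
alignment, since the triage rules consume hit tables, not raw searches.
One seeded generator drives the whole bundle: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from termite_virome import orf_codes
from termite_virome.io_formats import (
    ContigRecord,
    DomainHit,
    HomologyHit,
    LibraryMeta,
    ReferenceVirus,
    write_count_matrix,
    write_domain_table,
    write_fasta,
    write_homology_table,
    write_library_metadata,
    write_reference_table,
    write_truth,
)
from termite_virome.triage import VirusNamer

_SENSE_CODONS = [
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in {"TAA", "TAG", "TGA"}
]

# tier bounds as percent of total reads (strict high > 0.01, low <= 0.001);
# draws stay inside open intervals so rounding cannot cross a boundary
_TIER_PERCENT_RANGES = {
    "high": (0.011, 0.4),
    "moderate": (0.0011, 0.009),
    "low": (0.00012, 0.0009),
}

_SPECIES_POOL = [
    ("Occasitermes sp.", "Termitidae"),
    ("Coptotermes acinaciformis", "Rhinotermitidae"),
    ("Heterotermes ferox", "Rhinotermitidae"),
    ("Schedorhinotermes intermedius", "Rhinotermitidae"),
    ("Cryptotermes secundus", "Kalotermitidae"),
    ("Mastotermes darwiniensis", "Mastotermitidae"),
    ("Nasutitermes similis", "Termitidae"),
    ("Microcerotermes sp.", "Termitidae"),
    ("Embiratermes neotenicus", "Termitidae"),
    ("Epicalotermes kempae", "Kalotermitidae"),
]

_HEAD_ONLY_COUNTRIES = ["French Guiana", "Cameroon", "Kenya", "Indonesia"]
_DIETS = ["Wood", "Soil", "Grass", "Litter"]

# clade, group, relative host category, typical reference genome length
_CLADE_POOL = [
    ("Negev-like", "Hepe-Virga", "arthropod", 10400),
    ("Sobemo-like", "Luteo-Sobemo", "arthropod", 2800),
    ("Lispi-like", "Mono-Chu", "arthropod", 11000),
    ("Bunya-like", "Bunya-Arena", "arthropod", 6600),
    ("Iflaviridae", "Picorna-Calici", "arthropod", 9600),
    ("Idaeovirus-like", "Hepe-Virga", "plant", 5500),
    ("Mitovirus-like", "Narna-Levi", "fungi", 2600),
    ("Leviviridae", "Narna-Levi", "bacteria", 3500),
    ("Picobirna-like A", "Partiti-Picobirna", "vertebrate", 1900),
    ("Narna-like", "Narna-Levi", "mixed", 3200),
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults are a desk-scale twin of the survey: 10 libraries with
    1e5–1e6 reads each, 20 viruses on 1–12 kb contigs, a high/moderate/
    low tier mix, a few endogenized copies and index-hop events.
    """

    n_libraries: int = 10
    n_viruses: int = 20
    procedure_split: float = 0.4  # fraction of libraries tagged head-only
    abundance_tier_mix: tuple = (0.3, 0.4, 0.3)  # high, moderate, low
    n_endogenous: int = 3
    n_index_hops: int = 2
    index_hop_fraction: float = 0.0005
    variant_code_fraction: float = 0.15
    seed: int = 0
    n_nonviral: int = 6
    include_contaminant: bool = True
    include_dna_virus: bool = True

    def __post_init__(self):
        for name in ("procedure_split", "index_hop_fraction", "variant_code_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.n_libraries < 1:
            raise ConfigurationError("n_libraries must be >= 1")
        if min(self.abundance_tier_mix) < 0 or not np.isclose(
            sum(self.abundance_tier_mix), 1.0
        ):
            raise ConfigurationError("abundance_tier_mix must be proportions summing to 1")
        if self.n_viruses < 0 or self.n_endogenous < 0 or self.n_index_hops < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_index_hops > 0:
            if not 0.0 < self.index_hop_fraction < 0.001:
                raise ConfigurationError(
                    "index_hop_fraction must be in (0, 0.001) for planted hops "
                    "to be removable under the 0.1% rule"
                )
            if self.n_libraries < 2:
                raise ConfigurationError("index hops need at least 2 libraries")
            if self.n_index_hops > self.n_viruses:
                raise ConfigurationError("more index hops than viruses")
        if self.n_endogenous > 0 and self.n_viruses == 0:
            raise ConfigurationError("endogenous copies need source viruses")


@dataclass
class GroundTruth:
    """What was planted, for exact recovery scoring."""

    contig_labels: dict  # contig_id -> exogenous-viral|endogenous|non-viral|contaminant-blacklist
    virus_of_contig: dict  # contig_id -> matrix row name
    virus_hosts: dict  # virus name -> planted host category
    virus_code: dict  # virus name -> genetic code id
    detections: dict  # "virus|library" -> resident|index-hop
    hop_sources: dict  # "virus|target_library" -> source library
    viral_fraction: dict  # library -> column sum / total reads
    exogenous_viruses: list
    endogenous_viruses: list
    excluded_other: list  # contaminant / DNA-virus row names

    def to_json(self) -> dict:
        return {
            "contig_labels": self.contig_labels,
            "virus_of_contig": self.virus_of_contig,
            "virus_hosts": self.virus_hosts,
            "virus_code": self.virus_code,
            "detections": self.detections,
            "hop_sources": self.hop_sources,
            "viral_fraction": self.viral_fraction,
            "exogenous_viruses": self.exogenous_viruses,
            "endogenous_viruses": self.endogenous_viruses,
            "excluded_other": self.excluded_other,
        }


@dataclass
class SimulatedBundle:
    """In-memory bundle; ``write`` materializes the on-disk formats."""

    config: SimulationConfig
    contigs: list
    homology_hits: list
    domain_hits: list
    count_matrix: pd.DataFrame
    library_meta: list
    reference_table: dict
    virus_contigs: pd.DataFrame  # virus_name, contig_id, contig_length
    truth: GroundTruth

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": out / "contigs.fasta",
            "homology": out / "homology_hits.tsv",
            "domains": out / "domain_hits.tsv",
            "counts": out / "count_matrix.tsv",
            "metadata": out / "library_metadata.tsv",
            "references": out / "reference_viruses.tsv",
            "virus_contigs": out / "virus_contigs.tsv",
            "truth": out / "ground_truth.json",
        }
        write_fasta(self.contigs, paths["contigs"])
        write_homology_table(self.homology_hits, paths["homology"])
        write_domain_table(self.domain_hits, paths["domains"])
        write_count_matrix(self.count_matrix, paths["counts"])
        write_library_metadata(self.library_meta, paths["metadata"])
        write_reference_table(self.reference_table.values(), paths["references"])
        self.virus_contigs.to_csv(paths["virus_contigs"], sep="\t", index=False)
        write_truth(self.truth.to_json(), paths["truth"])
        return paths


def _random_codons(rng, n: int) -> list:
    return [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n)]


def make_viral_genome(
    rng: np.random.Generator, length: int, variant_code: bool = False
) -> tuple[str, tuple[int, int], int]:
    """Random genome with one planted replicase ORF spanning most of it.

    Returns (sequence, orf_span incl. terminal stop, code_id).  With
    ``variant_code`` several internal TGA codons are planted so the ORF
    is intact only under a UGA=Trp table (4); otherwise the ORF is clean
    under the standard code (1).
    """
    if length < 700:
        raise ValueError("genome length must be >= 700 nt")
    utr5 = int(rng.integers(30, 120))
    utr3 = int(rng.integers(30, 120))
    n_codons = (length - utr5 - utr3) // 3 - 2  # minus start and stop
    if n_codons < 200:
        raise ValueError("genome too short for a gene-sized ORF")
    codons = _random_codons(rng, n_codons)
    code_id = 1
    if variant_code:
        code_id = 4
        n_tga = int(rng.integers(3, 7))
        # first TGA early so the standard-code ORF covers < half the span
        positions = sorted(
            set(
                [int(rng.integers(n_codons // 10, int(n_codons * 0.40)))]
                + [int(p) for p in rng.integers(n_codons // 10, n_codons - 10, n_tga - 1)]
            )
        )
        for p in positions:
            codons[p] = "TGA"
    orf = "ATG" + "".join(codons) + "TAA"
    head = "".join(_random_codons(rng, utr5 // 3 + 1))[:utr5]
    tail = "".join(_random_codons(rng, utr3 // 3 + 1))[:utr3]
    seq = head + orf + tail
    return seq, (utr5, utr5 + len(orf)), code_id


def plant_endogenous_copy(
    genome: str,
    n_indels: int,
    seed: int,
    homology_span: tuple[int, int] | None = None,
) -> str:
    """Degrade a viral genome into an endogenized copy by planting
    ``n_indels`` single-base insertions/deletions inside the replicase
    homology span.  Every single-base indel shifts the reading frame, so
    the ORF prediction is interrupted downstream of the first one.

    With no span given, the longest ORF (any supported UGA=Trp-aware
    code, >= 200 codons) defines the replicase region; a genome without
    such an ORF is rejected.
    """
    if n_indels < 1:
        raise ValueError("n_indels must be >= 1; zero indels would not be endogenized")
    if len(genome) <= 300:
        raise ValueError("genome too short to endogenize")
    if homology_span is None:
        best = None
        for code_id in (1, 4):
            orfs = orf_codes.find_orfs(genome, code_id, min_len_codons=200)
            if orfs and (best is None or orfs[0].length_codons > best.length_codons):
                best = orfs[0]
        if best is None:
            raise ValueError("no gene-sized ORF (>= 200 codons) to interrupt")
        homology_span = (best.start, best.end)
    s, e = homology_span
    span_len = e - s
    # indels stay in the interior of the span so the flanking ORF
    # fragments each fall well below the 0.9 single-ORF coverage rule;
    # a lone indel sits near the middle so neither fragment keeps half
    if n_indels == 1:
        lo, hi = s + int(span_len * 0.42), s + int(span_len * 0.58)
    else:
        lo, hi = s + int(span_len * 0.2), s + int(span_len * 0.8)
    if hi - lo < n_indels:
        raise ValueError("homology span too short for requested indels")
    # a nearby insertion/deletion pair can restore the frame with no stop
    # in the garbled gap, leaving the ORF intact; redraw until the copy is
    # genuinely interrupted (and halved) under both stop-codon repertoires
    for attempt in range(64):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        positions = sorted(
            int(p) for p in rng.choice(np.arange(lo, hi), size=n_indels, replace=False)
        )
        seq = genome
        offset = 0
        for p in positions:
            p += offset
            if rng.random() < 0.5:
                seq = seq[:p] + seq[p + 1 :]  # deletion
                offset -= 1
            else:
                base = "ACGT"[rng.integers(4)]
                seq = seq[:p] + base + seq[p:]  # insertion
                offset += 1
        out_span = (s, min(e + offset, len(seq)))
        # a single frameshift always leaves one flank (plus stop-codon
        # readthrough) intact, so the longest surviving ORF can only be
        # pushed below ~0.7 of the original, not below half
        degraded = True
        for code_id in (1, 4):
            orfs = orf_codes.find_orfs(seq, code_id, min_len_codons=30)
            hit, _ = orf_codes.detect_interrupted_orf(out_span, orfs)
            longest = orfs[0].length_codons if orfs else 0
            degraded = degraded and hit and longest < 0.7 * (span_len / 3)
        if degraded:
            return seq
    raise RuntimeError("could not interrupt ORF; span may be degenerate")


def plant_index_hop(
    count_matrix: pd.DataFrame,
    virus: str,
    source_library: str,
    target_library: str,
    fraction: float,
) -> pd.DataFrame:
    """Plant one cross-library contamination event.

    The target cell becomes ``round(fraction * source_count)`` with a
    floor of one read; every other cell is unchanged.
    """
    if fraction <= 0:
        raise ValueError("hop fraction must be positive")
    src = int(count_matrix.loc[virus, source_library])
    if src <= 0:
        raise ValueError("source library has no reads for this virus")
    out = count_matrix.copy()
    out.loc[virus, target_library] = max(1, round(fraction * src))
    return out


def _build_reference_pool(config: SimulationConfig) -> dict:
    refs: dict[str, ReferenceVirus] = {}
    for i, (clade, group, host, length) in enumerate(_CLADE_POOL):
        acc = f"REF{i:04d}"
        refs[acc] = ReferenceVirus(
            accession=acc,
            name=f"{clade} reference virus {i + 1}",
            host_category=host,
            genome_length=length,
            clade=clade,
            group=group,
            nucleic_acid="RNA",
        )
    if config.include_contaminant:
        refs["REFC001"] = ReferenceVirus(
            "REFC001", "bovine viral diarrhea virus 1", "vertebrate",
            12300, "unassigned", "unassigned", "RNA",
        )
    if config.include_dna_virus:
        refs["REFD001"] = ReferenceVirus(
            "REFD001", "termite-associated entomopoxvirus", "arthropod",
            230000, "unassigned", "unassigned", "DNA",
        )
    return refs


def _assign_tiers(rng, config: SimulationConfig) -> list:
    """One tier per virus, honoring the configured mix; index-hop source
    viruses (the first n_index_hops) are forced to the high tier."""
    n = config.n_viruses
    n_high = int(round(config.abundance_tier_mix[0] * n))
    n_mod = int(round(config.abundance_tier_mix[1] * n))
    n_high = max(n_high, config.n_index_hops)
    n_mod = min(n_mod, n - n_high)
    tiers = ["high"] * n_high + ["moderate"] * n_mod + ["low"] * (n - n_high - n_mod)
    body = tiers[config.n_index_hops :]
    rng.shuffle(body)
    return tiers[: config.n_index_hops] + body


def _draw_evalue(rng) -> float:
    return float(10.0 ** rng.uniform(-180, -8))


def simulate_virome(config: SimulationConfig) -> SimulatedBundle:
    """Generate a full synthetic bundle under one seeded random stream."""
    rng = np.random.default_rng(config.seed)
    n_head = int(round(config.procedure_split * config.n_libraries))

    # --- libraries -------------------------------------------------------
    libs: list[LibraryMeta] = []
    for i in range(config.n_libraries):
        lib_id = f"lib{i + 1:02d}"
        species, family = _SPECIES_POOL[i % len(_SPECIES_POOL)]
        head_only = i < n_head
        libs.append(
            LibraryMeta(
                library_id=lib_id,
                termite_species=species,
                termite_family=family,
                country=(
                    _HEAD_ONLY_COUNTRIES[int(rng.integers(len(_HEAD_ONLY_COUNTRIES)))]
                    if head_only
                    else "Australia"
                ),
                diet=_DIETS[int(rng.integers(len(_DIETS)))],
                procedure="head-only" if head_only else "whole-body",
                total_reads=int(rng.integers(200_000, 1_000_001)),
            )
        )
    lib_ids = [m.library_id for m in libs]
    totals = {m.library_id: m.total_reads for m in libs}

    refs = _build_reference_pool(config)
    rna_refs = [r for r in refs.values() if r.nucleic_acid == "RNA" and r.clade != "unassigned"]
    namer = VirusNamer(int(rng.integers(0, 2**31 - 1)))

    contigs: list[ContigRecord] = []
    hits: list[HomologyHit] = []
    domains: list[DomainHit] = []
    contig_labels: dict[str, str] = {}
    virus_of_contig: dict[str, str] = {}
    virus_hosts: dict[str, str] = {}
    virus_code: dict[str, int] = {}
    detections: dict[str, str] = {}
    hop_sources: dict[str, str] = {}
    exogenous: list[str] = []
    endogenous_names: list[str] = []
    excluded_other: list[str] = []
    vc_rows: list[dict] = []
    row_names: list[str] = []
    counts = pd.DataFrame(
        0, index=pd.Index([], name="virus", dtype=object), columns=lib_ids, dtype=int
    )
    contig_counter = [0]

    def new_contig_id(lib: str) -> str:
        contig_counter[0] += 1
        return f"{lib}__contig_{contig_counter[0]:04d}"

    def add_hit(cid, ref, span, seq_len):
        s, e = span
        hits.append(
            HomologyHit(
                query_id=cid,
                subject_accession=ref.accession,
                percent_identity=float(np.round(rng.uniform(20, 45), 1)),
                align_length=e - s,
                mismatch=int(rng.integers(50, 400)),
                gapopen=int(rng.integers(0, 12)),
                align_start=s,
                align_end=e,
                subject_start=1,
                subject_end=e - s,
                evalue=_draw_evalue(rng),
                bitscore=float(np.round(rng.uniform(80, 900), 1)),
                strand="+",
            )
        )

    def add_rdrp_domain(cid, span):
        s, e = span
        domains.append(
            DomainHit(
                cid, "cl02808", "RdRp, RNA-dependent RNA polymerase", True,
                s, max(s + 1, e - 3), _draw_evalue(rng),
            )
        )

    # --- exogenous viruses ----------------------------------------------
    tiers = _assign_tiers(rng, config)
    genome_by_virus: dict[str, tuple[str, tuple[int, int]]] = {}
    ref_of_virus: dict[str, ReferenceVirus] = {}
    for v in range(config.n_viruses):
        name = namer.next_name()
        ref = rna_refs[int(rng.integers(len(rna_refs)))]
        variant = bool(rng.random() < config.variant_code_fraction)
        length = int(
            np.clip(round(ref.genome_length * rng.uniform(0.85, 1.0)), 1000, 12000)
        )
        seq, orf_span, code_id = make_viral_genome(rng, length, variant)
        tier = tiers[v]
        if v < config.n_index_hops:
            # hop sources must leave at least one library free for the hop
            n_libs_present = min(2, config.n_libraries - 1)
        else:
            n_libs_present = int(rng.integers(1, min(3, config.n_libraries) + 1))
        present = sorted(
            rng.choice(lib_ids, size=n_libs_present, replace=False).tolist()
        )
        # the contig is assembled in the library where the virus is deepest
        home = present[0]
        cid = new_contig_id(home)
        contigs.append(ContigRecord(cid, home, seq))
        add_hit(cid, ref, orf_span, len(seq))
        add_rdrp_domain(cid, orf_span)

        if tier == "high" and v < config.n_index_hops:
            # dominant hop-source virus: counts large enough that a
            # sub-0.1% hop still rounds to >= 1 read
            pcts = {lib: rng.uniform(1.0, 3.0) for lib in present}
        else:
            lo, hi = _TIER_PERCENT_RANGES[tier]
            base = rng.uniform(lo, hi)
            pcts = {lib: np.clip(base * rng.uniform(0.7, 1.4), lo, hi) for lib in present}
        counts.loc[name] = 0
        for lib in present:
            c = max(1, int(round(pcts[lib] / 100.0 * totals[lib])))
            counts.loc[name, lib] = c
            detections[f"{name}|{lib}"] = "resident"
        contig_labels[cid] = "exogenous-viral"
        virus_of_contig[cid] = name
        virus_hosts[name] = ref.host_category
        virus_code[name] = code_id
        exogenous.append(name)
        row_names.append(name)
        genome_by_virus[name] = (seq, orf_span)
        ref_of_virus[name] = ref
        vc_rows.append({"virus_name": name, "contig_id": cid, "contig_length": len(seq)})

    # --- endogenized copies ---------------------------------------------
    source_pool = [n for n in exogenous if virus_code[n] == 1] or exogenous
    for k in range(config.n_endogenous):
        src_name = source_pool[k % len(source_pool)] if source_pool else None
        if src_name is None:
            break
        seq, orf_span = genome_by_virus[src_name]
        # truncate around the replicase first (completeness well below
        # 0.8), then plant frameshifting indels inside the kept span
        keep = int(len(seq) * rng.uniform(0.40, 0.55))
        start = max(0, orf_span[0] - 30)
        intact_frag = seq[start : start + keep]
        h_span = (
            max(0, orf_span[0] - start),
            min(len(intact_frag), orf_span[1] - start),
        )
        frag = plant_endogenous_copy(
            intact_frag, int(rng.integers(2, 5)), int(rng.integers(0, 2**31 - 1)), h_span
        )
        h_span = (h_span[0], min(h_span[1], len(frag)))
        name = namer.next_name()
        lib = lib_ids[int(rng.integers(len(lib_ids)))]
        cid = new_contig_id(lib)
        contigs.append(ContigRecord(cid, lib, frag))
        ref = ref_of_virus[src_name]
        add_hit(cid, ref, h_span, len(frag))
        add_rdrp_domain(cid, h_span)
        counts.loc[name] = 0
        c = max(1, int(round(rng.uniform(0.0002, 0.0008) / 100.0 * totals[lib])))
        counts.loc[name, lib] = c
        detections[f"{name}|{lib}"] = "resident"
        contig_labels[cid] = "endogenous"
        virus_of_contig[cid] = name
        virus_hosts[name] = "endogenous"
        virus_code[name] = 1
        endogenous_names.append(name)
        row_names.append(name)
        vc_rows.append({"virus_name": name, "contig_id": cid, "contig_length": len(frag)})

    # --- blacklist contaminant and DNA-virus hits ------------------------
    for flag, acc, label in (
        (config.include_contaminant, "REFC001", "contaminant-blacklist"),
        (config.include_dna_virus, "REFD001", "non-viral"),
    ):
        if not flag or config.n_viruses == 0:
            continue
        ref = refs[acc]
        seq, orf_span, _ = make_viral_genome(rng, int(rng.integers(2000, 5000)))
        name = namer.next_name()
        lib = lib_ids[int(rng.integers(len(lib_ids)))]
        cid = new_contig_id(lib)
        contigs.append(ContigRecord(cid, lib, seq))
        add_hit(cid, ref, orf_span, len(seq))
        add_rdrp_domain(cid, orf_span)
        counts.loc[name] = 0
        c = max(1, int(round(rng.uniform(0.002, 0.008) / 100.0 * totals[lib])))
        counts.loc[name, lib] = c
        detections[f"{name}|{lib}"] = "resident"
        contig_labels[cid] = label
        virus_of_contig[cid] = name
        virus_hosts[name] = ref.host_category
        virus_code[name] = 1
        excluded_other.append(name)
        row_names.append(name)
        vc_rows.append({"virus_name": name, "contig_id": cid, "contig_length": len(seq)})

    # --- non-viral decoys -------------------------------------------------
    for k in range(config.n_nonviral):
        lib = lib_ids[int(rng.integers(len(lib_ids)))]
        cid = new_contig_id(lib)
        length = int(rng.integers(600, 4000))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        contigs.append(ContigRecord(cid, lib, seq))
        contig_labels[cid] = "non-viral"
        if config.n_viruses == 0:
            continue  # empty-survey case: no hit tables at all
        kind = k % 3
        if kind == 0:
            pass  # no hits: dropped for lack of a credible viral hit
        elif kind == 1:
            # marginal hit above the e-value cutoff
            ref = rna_refs[int(rng.integers(len(rna_refs)))]
            span = (10, min(length - 10, 900))
            add_hit(cid, ref, span, length)
            hits[-1] = HomologyHit(
                **{**hits[-1].__dict__, "evalue": float(10.0 ** rng.uniform(-4.9, -2))}
            )
        else:
            # strong viral hit but a non-viral conserved domain: host gene
            ref = rna_refs[int(rng.integers(len(rna_refs)))]
            span = (10, min(length - 10, 900))
            add_hit(cid, ref, span, length)
            domains.append(
                DomainHit(
                    cid, "cl21455", "ABC transporter ATPase domain", False,
                    span[0], span[1], _draw_evalue(rng),
                )
            )

    # --- index hops -------------------------------------------------------
    for k in range(config.n_index_hops):
        virus = exogenous[k]
        row = counts.loc[virus]
        source = row.idxmax()
        absent = [l for l in lib_ids if row[l] == 0]
        target = absent[int(rng.integers(len(absent)))]
        counts = plant_index_hop(counts, virus, source, target, config.index_hop_fraction)
        detections[f"{virus}|{target}"] = "index-hop"
        hop_sources[f"{virus}|{target}"] = source

    counts = (counts.loc[row_names] if row_names else counts).astype(int)
    counts.index.name = "virus"
    viral_fraction = {
        lib: float(counts[lib].sum()) / totals[lib] if len(counts) else 0.0
        for lib in lib_ids
    }
    truth = GroundTruth(
        contig_labels=contig_labels,
        virus_of_contig=virus_of_contig,
        virus_hosts=virus_hosts,
        virus_code=virus_code,
        detections=detections,
        hop_sources=hop_sources,
        viral_fraction=viral_fraction,
        exogenous_viruses=exogenous,
        endogenous_viruses=endogenous_names,
        excluded_other=excluded_other,
    )
    return SimulatedBundle(
        config=config,
        contigs=contigs,
        homology_hits=hits,
        domain_hits=domains,
        count_matrix=counts,
        library_meta=libs,
        reference_table=refs,
        virus_contigs=pd.DataFrame(
            vc_rows, columns=["virus_name", "contig_id", "contig_length"]
        ),
        truth=truth,
    )
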