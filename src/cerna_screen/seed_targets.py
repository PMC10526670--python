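"""Canonical seed-match prediction of miRNA binding sites on 3'-UTRs.

Implements the standard canonical site taxonomy (8mer > 7mer-m8 > 7mer-A1 >
6mer) defined by perfect Watson-Crick pairing of the miRNA seed (positions
2-8, 1-based from the miRNA 5' end) to the UTR.  Coordinates are 0-based,
half-open, on the UTR read 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set

__all__ = [
    "MatureMiRNA",
    "UtrSequence",
    "SeedSite",
    "TargetMap",
    "SITE_CLASSES",
    "mature_from_probe",
    "reverse_complement_dna",
    "find_seed_sites",
    "predict_targets",
    "combine_predictions",
]

# Ranked weakest -> strongest; index is used for class comparisons.
SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_RNA_ALPHABET = set("ACGU")
_DNA_ALPHABET = set("ACGT")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: interval length on the UTR occupied by each site class
SITE_LENGTHS = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}


def class_rank(site_class: str) -> int:
    """Ordinal strength of a site class (higher = stronger)."""
    try:
        return SITE_CLASSES.index(site_class)
    except ValueError:
        raise ValueError(f"unknown site class: {site_class!r}") from None


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA, 5'->3', RNA alphabet, length >= 8."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(f"miRNA {self.id!r}: length {len(seq)} < 8")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"miRNA {self.id!r}: invalid characters {sorted(bad)}")

    @property
    def seed(self) -> str:
        """Seed region, miRNA positions 2-8 (1-based), 5'->3'."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class UtrSequence:
    """A 3'-UTR (or any target) sequence, normalized to upper-case DNA."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"UTR {self.id!r}: empty sequence")
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"UTR {self.id!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SeedSite:
    """A predicted binding site: [start, end) on the UTR, 5'->3'."""

    mirna: str
    utr: str
    start: int
    end: int
    site_class: str

    def __post_init__(self) -> None:
        expected = SITE_LENGTHS[self.site_class]
        if self.end - self.start != expected:
            raise ValueError(
                f"site [{self.start},{self.end}) has length {self.end - self.start}, "
                f"class {self.site_class} requires {expected}"
            )

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)


@dataclass
class TargetMap:
    """miRNA -> target gene edges with per-edge site provenance."""

    edges: Dict[str, Set[str]] = field(default_factory=dict)
    provenance: Dict[tuple, List[SeedSite]] = field(default_factory=dict)
    predictor: str = "canonical-seed"

    def add_site(self, site: SeedSite) -> None:
        self.edges.setdefault(site.mirna, set()).add(site.utr)
        self.provenance.setdefault((site.mirna, site.utr), []).append(site)

    def targets_of(self, mirna: str) -> Set[str]:
        return set(self.edges.get(mirna, set()))

    def all_targets(self, mirnas: Iterable[str] | None = None) -> Set[str]:
        keys = self.edges.keys() if mirnas is None else mirnas
        out: Set[str] = set()
        for m in keys:
            out |= self.edges.get(m, set())
        return out

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.edges.values())


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement over {A,C,G,T}; U is normalized to T first."""
    return seq.upper().replace("U", "T").translate(_DNA_COMPLEMENT)[::-1]


def mature_from_probe(probe: str) -> str:
    """Mature miRNA sequence (RNA) from an antisense DNA probe.

    The probe is the exact reverse complement of the mature miRNA, so the
    mature sequence is the reverse complement of the probe with T -> U.
    """
    if not probe:
        raise ValueError("empty probe sequence")
    up = probe.upper()
    for pos, ch in enumerate(up):
        if ch not in _DNA_ALPHABET:
            raise ValueError(f"invalid character {ch!r} at position {pos} in probe")
    return reverse_complement_dna(up).replace("T", "U")


def _seed_matches(mirna: MatureMiRNA) -> tuple:
    """(match7, match6): UTR-strand reverse complements of seed 2-8 and 2-7."""
    match7 = reverse_complement_dna(mirna.sequence[1:8])
    match6 = reverse_complement_dna(mirna.sequence[1:7])
    return match7, match6


def find_seed_sites(mirna: MatureMiRNA, utr: UtrSequence) -> List[SeedSite]:
    """Scan a UTR 5'->3' for canonical seed sites of one miRNA.

    Each seed-match occurrence is reported once with its best class:
    a 7-nt match to miRNA 2-8 followed on the UTR by A is an 8mer, otherwise
    a 7mer-m8; a 6-nt match to miRNA 2-7 (not already part of a 2-8 match)
    followed by A is a 7mer-A1, otherwise a 6mer.  Distinct match start
    positions are all reported, even when their intervals overlap.
    """
    match7, match6 = _seed_matches(mirna)
    seq = utr.sequence
    n = len(seq)
    sites: List[SeedSite] = []
    for i in range(n - 5):
        if seq[i : i + 7] == match7:
            if seq[i + 7 : i + 8] == "A":
                sites.append(SeedSite(mirna.id, utr.id, i, i + 8, "8mer"))
            else:
                sites.append(SeedSite(mirna.id, utr.id, i, i + 7, "7mer-m8"))
        elif seq[i : i + 6] == match6:
            # skip 6-mers subsumed by a 2-8 match one base upstream
            if i >= 1 and seq[i - 1 : i + 6] == match7:
                continue
            if seq[i + 6 : i + 7] == "A":
                sites.append(SeedSite(mirna.id, utr.id, i, i + 7, "7mer-A1"))
            else:
                sites.append(SeedSite(mirna.id, utr.id, i, i + 6, "6mer"))
    return sites


def predict_targets(
    mirnas: Sequence[MatureMiRNA],
    utrs: Sequence[UtrSequence],
    min_class: str = "6mer",
    predictor: str = "canonical-seed",
) -> TargetMap:
    """Build the miRNA -> gene target map from canonical seed matches.

    An edge (m, g) is present iff g's UTR carries at least one site of class
    >= ``min_class`` for m; all qualifying sites are kept as provenance.
    """
    min_rank = class_rank(min_class)
    tm = TargetMap(predictor=predictor)
    for m in mirnas:
        for u in utrs:
            for site in find_seed_sites(m, u):
                if class_rank(site.site_class) >= min_rank:
                    tm.add_site(site)
    return tm


def combine_predictions(a: TargetMap, b: TargetMap, mode: str = "union") -> TargetMap:
    """Combine two predictors' target maps per-miRNA (union or intersection)."""
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    if mode == "union":
        keys = set(a.edges) | set(b.edges)
    else:
        keys = set(a.edges) & set(b.edges)
    out = TargetMap(predictor=f"{a.predictor}+{b.predictor}:{mode}")
    for m in keys:
        ta, tb = a.edges.get(m, set()), b.edges.get(m, set())
        genes = (ta | tb) if mode == "union" else (ta & tb)
        if not genes:
            continue
        out.edges[m] = set(genes)
        for g in genes:
            prov = list(a.provenance.get((m, g), [])) + list(b.provenance.get((m, g), []))
            out.provenance[(m, g)] = prov
    return out
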