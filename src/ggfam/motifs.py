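"""Polyprenyl-synthase motif scanning and functional-class assignment.

Trans-prenyltransferases carry two aspartate-rich substrate-binding motifs,
FARM (DDxxxxD) and SARM (DDxxD), and — in the small subunits of heterodimeric
GPP synthases — one or two CxxxC subunit-interaction motifs whose spacer
positions are hydrophobic.  The presence/absence combination of these motifs
separates the family into functional classes: canonical GGPP synthases
(FARM + SARM + one CxxxC), putative polyprenyl pyrophosphate synthases
(FARM + SARM only), putative GPP synthases (FARM + SARM + two CxxxC),
a bifunctional GPS/GGPPS form carrying the CxxxS "prototype" of a second
CxxxC, and the two small-subunit classes SSU-I (no aspartate motifs, two
CxxxC) and SSU-II (FARM only, two CxxxC).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}

#: Default hydrophobic alphabet for the CxxxC/CxxxS spacer positions.
HYDROPHOBIC_DEFAULT = frozenset("AVLIMFWP")


class MotifKind(enum.Enum):
    FARM = "FARM"
    SARM = "SARM"
    CXXXC = "CXXXC"
    CXXXS = "CXXXS"


#: Window length of each motif kind.
MOTIF_LENGTH = {
    MotifKind.FARM: 7,
    MotifKind.SARM: 5,
    MotifKind.CXXXC: 5,
    MotifKind.CXXXS: 5,
}

#: Scan priority: earlier kinds claim spans first; later kinds may not overlap.
MOTIF_PRIORITY = [MotifKind.FARM, MotifKind.SARM, MotifKind.CXXXC, MotifKind.CXXXS]


class ArchClass(enum.Enum):
    """Functional classes defined by motif presence/absence."""

    CANONICAL_GGPPS = "CANONICAL_GGPPS"
    PH_PPPS = "PH_PPPS"
    PH_GPS_GGPPS = "PH_GPS_GGPPS"
    PH_GPS = "PH_GPS"
    PH_SSUI = "PH_SSUI"
    PH_SSUII = "PH_SSUII"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ProteinSequence:
    """One protein: unique id, free-text description, residue string.

    Residues are uppercase over the 20-letter amino-acid alphabet plus 'X'
    (unknown).  A terminal '*' stop is stripped at parse time.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal residue(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class MotifHit:
    kind: MotifKind
    start: int  # 0-based
    end: int  # half-open
    matched: str

    def __post_init__(self):
        if self.end - self.start != MOTIF_LENGTH[self.kind]:
            raise ValueError(
                f"{self.kind.value} hit must span {MOTIF_LENGTH[self.kind]} "
                f"residues, got [{self.start},{self.end})"
            )


@dataclass
class DomainArchitecture:
    sequence_id: str
    hits: list[MotifHit] = field(default_factory=list)

    @property
    def has_farm(self) -> bool:
        return any(h.kind is MotifKind.FARM for h in self.hits)

    @property
    def has_sarm(self) -> bool:
        return any(h.kind is MotifKind.SARM for h in self.hits)

    @property
    def n_cxxxc(self) -> int:
        return sum(h.kind is MotifKind.CXXXC for h in self.hits)

    @property
    def n_cxxxs(self) -> int:
        return sum(h.kind is MotifKind.CXXXS for h in self.hits)

    @property
    def klass(self) -> ArchClass:
        return classify_architecture(self.hits)


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file into :class:`ProteinSequence` records.

    Residues are uppercased and a single terminal ``*`` stop is stripped.
    Illegal residue characters and duplicate ids raise
    :class:`FastaParseError`; for illegal residues the error names the
    offending line number of the file.
    """
    path = Path(path)
    text = path.read_text()
    # validation pass over raw lines so errors can name line numbers
    in_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            in_record = True
            continue
        if not in_record:
            raise FastaParseError(
                f"{path}:{lineno}: sequence data before first '>' header"
            )
        residues = s.upper().rstrip("*")
        bad = set(residues) - ALPHABET
        if bad:
            raise FastaParseError(
                f"{path}:{lineno}: illegal residue character(s) "
                f"{sorted(bad)} in sequence line"
            )
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        records.append(
            ProteinSequence(id=rec.id, residues=residues, description=rec.description)
        )
    return records


def _matches_at(
    residues: str, pos: int, kind: MotifKind, hydrophobic: frozenset[str]
) -> bool:
    """'X' never matches any motif position, including the 'any' positions."""
    length = MOTIF_LENGTH[kind]
    if pos + length > len(residues):
        return False
    window = residues[pos : pos + length]
    if "X" in window:
        return False
    if kind is MotifKind.FARM:
        return window[0] == "D" and window[1] == "D" and window[6] == "D"
    if kind is MotifKind.SARM:
        return window[0] == "D" and window[1] == "D" and window[4] == "D"
    spacer_ok = all(c in hydrophobic for c in window[1:4])
    if kind is MotifKind.CXXXC:
        return window[0] == "C" and window[4] == "C" and spacer_ok
    if kind is MotifKind.CXXXS:
        return window[0] == "C" and window[4] == "S" and spacer_ok
    raise AssertionError(kind)


def find_motifs(
    seq: ProteinSequence, hydrophobic: frozenset[str] = HYDROPHOBIC_DEFAULT
) -> list[MotifHit]:
    """Scan one protein for FARM/SARM/CxxxC/CxxxS motifs.

    Motifs are claimed greedily left-to-right within each kind, kinds in
    priority order FARM > SARM > CXXXC > CXXXS; a later kind (or a later
    window of the same kind) may not overlap an already claimed span.  The
    returned hits are sorted by start position.
    """
    extra = set(hydrophobic) - AMINO_ACIDS
    if extra:
        raise ValueError(f"hydrophobic set contains non-amino-acid entries {sorted(extra)}")
    hydrophobic = frozenset(hydrophobic)
    claimed: list[tuple[int, int]] = []
    hits: list[MotifHit] = []
    for kind in MOTIF_PRIORITY:
        length = MOTIF_LENGTH[kind]
        for pos in range(len(seq.residues) - length + 1):
            end = pos + length
            if any(pos < ce and cs < end for cs, ce in claimed):
                continue
            if _matches_at(seq.residues, pos, kind, hydrophobic):
                claimed.append((pos, end))
                hits.append(
                    MotifHit(kind=kind, start=pos, end=end, matched=seq.residues[pos:end])
                )
    return sorted(hits, key=lambda h: h.start)


def classify_architecture(hits: list[MotifHit]) -> ArchClass:
    """Assign a functional class from motif presence/absence counts.

    Decision table, evaluated top-down, first match wins:

    ==========  ==========  =========  =========  ====================
    FARM        SARM        #CxxxC     #CxxxS     class
    ==========  ==========  =========  =========  ====================
    yes         yes         >= 2       --         PH_GPS
    yes         yes         1          >= 1       PH_GPS_GGPPS
    yes         yes         1          --         CANONICAL_GGPPS
    yes         yes         0          --         PH_PPPS
    no          no          >= 2       --         PH_SSUI
    yes         no          >= 2       --         PH_SSUII
    (anything else)                               UNCLASSIFIED
    ==========  ==========  =========  =========  ====================
    """
    farm = any(h.kind is MotifKind.FARM for h in hits)
    sarm = any(h.kind is MotifKind.SARM for h in hits)
    n_cc = sum(h.kind is MotifKind.CXXXC for h in hits)
    n_cs = sum(h.kind is MotifKind.CXXXS for h in hits)
    if farm and sarm and n_cc >= 2:
        return ArchClass.PH_GPS
    if farm and sarm and n_cc == 1 and n_cs >= 1:
        return ArchClass.PH_GPS_GGPPS
    if farm and sarm and n_cc == 1:
        return ArchClass.CANONICAL_GGPPS
    if farm and sarm and n_cc == 0:
        return ArchClass.PH_PPPS
    if not farm and not sarm and n_cc >= 2:
        return ArchClass.PH_SSUI
    if farm and not sarm and n_cc >= 2:
        return ArchClass.PH_SSUII
    return ArchClass.UNCLASSIFIED


def summarize_classes(archs: list[DomainArchitecture]) -> pd.DataFrame:
    """Count architectures per functional class, rows in enum order."""
    counts = {k: 0 for k in ArchClass}
    for a in archs:
        counts[a.klass] += 1
    return pd.DataFrame(
        {"klass": [k.value for k in ArchClass], "count": [counts[k] for k in ArchClass]}
    )


def architecture_table(archs: list[DomainArchitecture]) -> pd.DataFrame:
    """Flat per-sequence table (the `ggfam scan` TSV)."""
    rows = []
    for a in archs:
        rows.append(
            {
                "sequence_id": a.sequence_id,
                "has_farm": a.has_farm,
                "has_sarm": a.has_sarm,
                "n_cxxxc": a.n_cxxxc,
                "n_cxxxs": a.n_cxxxs,
                "class": a.klass.value,
                "hits": ";".join(
                    f"{h.kind.value}@{h.start}-{h.end}" for h in a.hits
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "has_farm",
            "has_sarm",
            "n_cxxxc",
            "n_cxxxs",
            "class",
            "hits",
        ],
    )


def scan_fasta(
    path: str | Path, hydrophobic: frozenset[str] = HYDROPHOBIC_DEFAULT
) -> list[DomainArchitecture]:
    """Convenience: read a FASTA and scan every record."""
    return [
        DomainArchitecture(sequence_id=s.id, hits=find_motifs(s, hydrophobic))
        for s in read_fasta(path)
    ]
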