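"""Bacterial-colony bisulfite sequencing analysis (QUMA-style).

Each sequenced colony is one cloned bisulfite-PCR molecule.  Against the
amplicon reference, a CpG cytosine read as C is methylated and as T is
unmethylated; cytosines outside CpG context should all convert to T, so
any retained non-CpG C is a conversion failure.  The set of retained
non-CpG C positions is a per-molecule fingerprint: clones sharing both the
CpG pattern and the fingerprint are indistinguishable molecules and are
collapsed to one unique clone with a multiplicity.  The clone-set
methylation percentage counts methylated CpG states over unique clones
only (multiplicities are bookkeeping, not weight).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .stats import star_label, two_tailed_ttest

__all__ = [
    "AmpliconReference",
    "BisulfiteClone",
    "call_clone",
    "deduplicate_clones",
    "clone_set_methylation",
    "compare_clone_methylation",
    "render_lollipop_matrix",
    "parse_lollipop_matrix",
    "clones_frame",
]


@dataclass
class AmpliconReference:
    """A bisulfite-PCR amplicon with its cytosine partition.

    ``cpg_indices`` are the 0-based positions of CpG cytosines (each must
    be a C followed by G), ``non_cpg_c_indices`` every other C.  Both are
    derived from the sequence when not given.
    """

    name: str
    sequence: str
    cpg_indices: list[int] = field(default_factory=list)
    non_cpg_c_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        seq = self.sequence
        if not self.cpg_indices and not self.non_cpg_c_indices:
            self.cpg_indices = [
                i for i, b in enumerate(seq)
                if b == "C" and i + 1 < len(seq) and seq[i + 1] == "G"
            ]
            cpg = set(self.cpg_indices)
            self.non_cpg_c_indices = [
                i for i, b in enumerate(seq) if b == "C" and i not in cpg
            ]
        if set(self.cpg_indices) & set(self.non_cpg_c_indices):
            raise ValueError(f"{self.name}: overlapping C index sets")
        for i in self.cpg_indices:
            if seq[i] != "C":
                raise ValueError(f"{self.name}: CpG index {i} is not a C")
            if i + 1 >= len(seq) or seq[i + 1] != "G":
                raise ValueError(f"{self.name}: CpG index {i} lacks the G at {i + 1}")
        for i in self.non_cpg_c_indices:
            if seq[i] != "C":
                raise ValueError(f"{self.name}: non-CpG C index {i} is not a C")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_indices)


@dataclass
class BisulfiteClone:
    """One (possibly collapsed) sequenced colony."""

    clone_id: str
    amplicon: str
    #: methylation state per CpG, in amplicon cpg_indices order (1/0)
    cpg_pattern: tuple[int, ...]
    #: retained (unconverted) non-CpG C positions — the uniqueness fingerprint
    fingerprint: frozenset[int]
    multiplicity: int = 1
    conversion_rate: float = 1.0
    identity: float = 1.0
    qc_pass: bool = True
    qc_reason: str = ""


def call_clone(read_id: str, read: str, reference: AmpliconReference,
               min_conversion: float = 0.95,
               min_identity: float = 0.9) -> BisulfiteClone:
    """Call one colony read against the amplicon reference.

    Positional comparison at amplicon scale (reads must be full-length).
    At each CpG cytosine, C means methylated, T unmethylated; any retained
    non-CpG C joins the fingerprint.  The conversion rate is the fraction
    of non-CpG cytosines that converted to T.  A clone fails QC — flagged,
    never silently dropped — when the read length differs from the
    reference, sequence identity outside cytosine positions falls below
    ``min_identity``, or conversion falls below ``min_conversion``.
    """
    read = read.upper()
    ref = reference.sequence
    if len(read) != len(ref):
        return BisulfiteClone(
            clone_id=read_id, amplicon=reference.name, cpg_pattern=(),
            fingerprint=frozenset(), conversion_rate=0.0, identity=0.0,
            qc_pass=False,
            qc_reason=f"length {len(read)} != reference {len(ref)}",
        )
    c_positions = set(reference.cpg_indices) | set(reference.non_cpg_c_indices)
    other = [i for i in range(len(ref)) if i not in c_positions]
    if other:
        matches = sum(read[i] == ref[i] for i in other)
        identity = matches / len(other)
    else:
        identity = 1.0

    pattern = []
    for i in reference.cpg_indices:
        pattern.append(1 if read[i] == "C" else 0)
    fingerprint = frozenset(i for i in reference.non_cpg_c_indices if read[i] == "C")
    n_non_cpg = len(reference.non_cpg_c_indices)
    conversion = 1.0 - len(fingerprint) / n_non_cpg if n_non_cpg else 1.0

    qc_pass = True
    reason = ""
    if identity < min_identity:
        qc_pass, reason = False, f"identity {identity:.3f} < {min_identity}"
    elif conversion < min_conversion:
        qc_pass, reason = False, f"conversion {conversion:.3f} < {min_conversion}"
    return BisulfiteClone(
        clone_id=read_id, amplicon=reference.name,
        cpg_pattern=tuple(pattern), fingerprint=fingerprint,
        conversion_rate=conversion, identity=identity,
        qc_pass=qc_pass, qc_reason=reason,
    )


def deduplicate_clones(clones: list[BisulfiteClone]) -> list[BisulfiteClone]:
    """Collapse indistinguishable clones, accumulating multiplicities.

    Clones are duplicates when they share both the CpG methylation pattern
    and the unconverted-C fingerprint (clones differing only at non-C
    positions are separated upstream by QC identity).  QC-failing clones
    are excluded.  The sum of output multiplicities equals the number of
    QC-passing inputs.
    """
    passing = [c for c in clones if c.qc_pass]
    if not passing:
        return []
    amplicons = {c.amplicon for c in passing}
    if len(amplicons) > 1:
        raise ValueError(f"clones from mixed amplicons: {sorted(amplicons)}")
    groups: dict[tuple, list[BisulfiteClone]] = {}
    for clone in passing:
        groups.setdefault((clone.cpg_pattern, clone.fingerprint), []).append(clone)
    unique = []
    for members in groups.values():
        rep = members[0]
        unique.append(BisulfiteClone(
            clone_id=rep.clone_id, amplicon=rep.amplicon,
            cpg_pattern=rep.cpg_pattern, fingerprint=rep.fingerprint,
            multiplicity=sum(m.multiplicity for m in members),
            conversion_rate=rep.conversion_rate, identity=rep.identity,
            qc_pass=True,
        ))
    return unique


def clone_set_methylation(unique_clones: list[BisulfiteClone]) -> float:
    """Clone-set methylation percentage over unique clones.

    100 x (methylated CpG states) / (all CpG states), counting each unique
    clone once — multiplicities are deliberately not weighted in.
    """
    if not unique_clones:
        raise ValueError("clone_set_methylation: empty clone set")
    methylated = sum(sum(c.cpg_pattern) for c in unique_clones)
    total = sum(len(c.cpg_pattern) for c in unique_clones)
    if total == 0:
        raise ValueError("clone_set_methylation: clones carry no CpG sites")
    return 100.0 * methylated / total


def compare_clone_methylation(group_a, group_b) -> tuple[float, str]:
    """Two-tailed Student's t-test on per-embryo clone-set percentages.

    Returns (p_value, star label) with stars at 0.05/0.01/0.001 and 'ns'
    otherwise.  Each group needs at least two embryos.
    """
    p = two_tailed_ttest(group_a, group_b)
    return p, star_label(p)


def render_lollipop_matrix(unique_clones: list[BisulfiteClone]) -> pd.DataFrame:
    """Lollipop-figure matrix: one row per unique clone, one column per CpG.

    Cells are 1 (methylated, the filled circle) or 0 (unmethylated, open
    circle); the ``multiplicity`` column carries the duplicate count shown
    in front of each clone row.
    """
    if not unique_clones:
        raise ValueError("render_lollipop_matrix: empty clone set")
    n_cpg = len(unique_clones[0].cpg_pattern)
    rows = []
    for clone in unique_clones:
        row: dict = {"clone_id": clone.clone_id, "multiplicity": clone.multiplicity}
        for j, state in enumerate(clone.cpg_pattern):
            row[f"cpg_{j + 1}"] = state
        rows.append(row)
    cols = ["clone_id", "multiplicity"] + [f"cpg_{j + 1}" for j in range(n_cpg)]
    return pd.DataFrame(rows, columns=cols)


def parse_lollipop_matrix(matrix: pd.DataFrame, amplicon: str = "") -> list[BisulfiteClone]:
    """Inverse of :func:`render_lollipop_matrix` (fingerprints are not
    representable in the matrix and come back empty)."""
    cpg_cols = [c for c in matrix.columns if c.startswith("cpg_")]
    return [
        BisulfiteClone(
            clone_id=str(row["clone_id"]), amplicon=amplicon,
            cpg_pattern=tuple(int(row[c]) for c in cpg_cols),
            fingerprint=frozenset(), multiplicity=int(row["multiplicity"]),
        )
        for _, row in matrix.iterrows()
    ]


def clones_frame(clones: list[BisulfiteClone]) -> pd.DataFrame:
    """Tabulate clones for TSV export (pattern/fingerprint as compact text)."""
    return pd.DataFrame([{
        "clone_id": c.clone_id,
        "amplicon": c.amplicon,
        "multiplicity": c.multiplicity,
        "conversion_rate": c.conversion_rate,
        "identity": c.identity,
        "qc_pass": c.qc_pass,
        "qc_reason": c.qc_reason,
        "cpg_pattern": "".join(map(str, c.cpg_pattern)),
        "fingerprint": ",".join(map(str, sorted(c.fingerprint))),
    } for c in clones])
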