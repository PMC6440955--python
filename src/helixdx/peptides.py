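"""Peptide definitions in the C99 numbering frame.

The peptides studied here are fragments of the amyloid precursor protein
C99 transmembrane domain.  Residue numbers refer to C99 positions (so the
familiar landmarks keep their names: the G37/G38 hinge, T43/T48
back-bonding threonines, the epsilon-cleavage sites L49/V50 and T48/L49).
Termini may be blocked (N-acetylation / C-amidation), which matters both
for intrinsic exchange rates and for which backbone amides exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence anchored in the C99 numbering frame.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"A26-55_WT"``.
    sequence : str
        One-letter amino-acid sequence, N to C.
    first_residue_number : int
        C99 number of the first residue (26 or 28 for the peptides here).
    n_terminal : {"acetylated", "free"}
    c_terminal : {"amidated", "free"}
    mutations : tuple of (position, original, replacement)
        Mutations already applied to ``sequence`` (bookkeeping only).
    """

    name: str
    sequence: str
    first_residue_number: int
    n_terminal: str = "free"
    c_terminal: str = "free"
    mutations: tuple = field(default_factory=tuple)

    def __post_init__(self):
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValueError(f"non-canonical residue letter(s): {sorted(bad)}")
        if self.n_terminal not in ("acetylated", "free"):
            raise ValueError(f"bad n_terminal: {self.n_terminal!r}")
        if self.c_terminal not in ("amidated", "free"):
            raise ValueError(f"bad c_terminal: {self.c_terminal!r}")
        for pos, orig, new in self.mutations:
            if not (self.first_residue_number <= pos <= self.last_residue_number):
                raise ValueError(f"mutation position {pos} outside numbering span")
            if self.residue_at(pos) != new:
                raise ValueError(
                    f"mutation {orig}{pos}{new} inconsistent with sequence"
                )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + self.n_residues - 1

    @property
    def residue_numbers(self):
        return list(range(self.first_residue_number, self.last_residue_number + 1))

    def residue_at(self, number: int) -> str:
        return self.sequence[number - self.first_residue_number]

    def index_of(self, number: int) -> int:
        if not (self.first_residue_number <= number <= self.last_residue_number):
            raise KeyError(f"residue {number} outside {self.name}")
        return number - self.first_residue_number

    def mutate(self, name: str, *mutations: str) -> "PeptideSpec":
        """Apply point mutations given as e.g. ``"I45T"``."""
        seq = list(self.sequence)
        records = list(self.mutations)
        for m in mutations:
            orig, pos, new = m[0], int(m[1:-1]), m[-1]
            i = self.index_of(pos)
            if seq[i] != orig:
                raise ValueError(f"{m}: position {pos} is {seq[i]}, not {orig}")
            seq[i] = new
            records.append((pos, orig, new))
        return replace(
            self, name=name, sequence="".join(seq), mutations=tuple(records)
        )

    def amide_residue_numbers(self) -> list[int]:
        """C99 numbers of residues carrying an observable backbone amide.

        Prolines have no amide NH.  With a free N-terminus residue 1 has an
        alpha-amine rather than a peptide amide (and residue 2 exchanges too
        fast to observe), so the first two positions are dropped; under
        N-acetylation residue 1's amide exists and is kept.
        """
        first = self.first_residue_number
        skip = set()
        if self.n_terminal == "free":
            skip.update((first, first + 1))
        return [
            n
            for n in self.residue_numbers
            if self.residue_at(n) != "P" and n not in skip
        ]


# Table-1 peptides.  The I45T mutants are built from WT via the stated point
# mutation; the A28-55 constructs replace S26/N27 with the KK solubility tag.
A26_55_WT = PeptideSpec(
    name="A26-55_WT",
    sequence="SNKGAIIGLMVGGVVIATVIVITLVMLKKK",
    first_residue_number=26,
    n_terminal="acetylated",
    c_terminal="amidated",
)
A26_55_I45T = A26_55_WT.mutate("A26-55_I45T", "I45T")
A28_55_WT = A26_55_WT.mutate("A28-55_WT", "S26K", "N27K")
A28_55_I45T = A28_55_WT.mutate("A28-55_I45T", "I45T")

PEPTIDES = {
    p.name: p for p in (A26_55_WT, A26_55_I45T, A28_55_WT, A28_55_I45T)
}
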