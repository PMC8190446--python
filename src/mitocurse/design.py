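"""Factorial panel design: haplotype/background labels, coevolved pairs, missing cells.

A mitonuclear panel crosses every mitochondrial haplotype into every isogenic
nuclear background.  Each nuclear background has exactly one *native*
(coevolved) haplotype; every other combination is *disrupted*.  Some
combinations may be inviable and therefore absent from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class DesignError(ValueError):
    """Raised when a panel design violates its structural invariants."""


@dataclass(frozen=True)
class PanelDesign:
    """A full-factorial mitonuclear cross with optional missing cells.

    Parameters
    ----------
    mito_labels : tuple of str
        Ordered mitochondrial haplotype identifiers.
    nuc_labels : tuple of str
        Ordered nuclear background identifiers.
    coevolved : dict
        Map ``nuclear label -> native mitochondrial label``.
    incompatible : frozenset of (nuc, mito) pairs
        Cells excluded from the panel (inviable combinations).
    """

    mito_labels: tuple[str, ...]
    nuc_labels: tuple[str, ...]
    coevolved: dict[str, str]
    incompatible: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mito_labels", tuple(self.mito_labels))
        object.__setattr__(self, "nuc_labels", tuple(self.nuc_labels))
        object.__setattr__(self, "coevolved", dict(self.coevolved))
        object.__setattr__(
            self, "incompatible", frozenset(tuple(p) for p in self.incompatible)
        )
        if not self.mito_labels or not self.nuc_labels:
            raise DesignError("label lists must be non-empty")
        if len(set(self.mito_labels)) != len(self.mito_labels):
            raise DesignError("duplicate mitochondrial labels")
        if len(set(self.nuc_labels)) != len(self.nuc_labels):
            raise DesignError("duplicate nuclear labels")
        for nuc, mito in self.coevolved.items():
            if nuc not in self.nuc_labels:
                raise DesignError(f"coevolved map names unknown nucleus {nuc!r}")
            if mito not in self.mito_labels:
                raise DesignError(f"coevolved map names unknown haplotype {mito!r}")
            if (nuc, mito) in self.incompatible:
                raise DesignError(
                    f"coevolved pair ({nuc}, {mito}) cannot be incompatible"
                )
        for nuc, mito in self.incompatible:
            if nuc not in self.nuc_labels or mito not in self.mito_labels:
                raise DesignError(f"incompatible cell ({nuc}, {mito}) outside design")

    @property
    def n_total_genotypes(self) -> int:
        """Genotype count of the complete factorial, before removing cells."""
        return len(self.mito_labels) * len(self.nuc_labels)

    @property
    def n_genotypes(self) -> int:
        """Number of analysable genotypes (factorial minus incompatible cells)."""
        return self.n_total_genotypes - len(self.incompatible)

    @property
    def n_coevolved(self) -> int:
        return len(self.coevolved)

    @property
    def n_disrupted(self) -> int:
        """Disrupted genotypes in the complete factorial (before removals)."""
        return self.n_total_genotypes - self.n_coevolved

    def cells(self) -> list[tuple[str, str]]:
        """All viable (nuc, mito) cells in design order."""
        return [
            (n, m)
            for n in self.nuc_labels
            for m in self.mito_labels
            if (n, m) not in self.incompatible
        ]

    def is_coevolved(self, nuc: str, mito: str) -> bool:
        return self.coevolved.get(nuc) == mito

    @classmethod
    def fully_crossed(
        cls,
        labels: "list[str] | tuple[str, ...]",
        incompatible: "set[tuple[str, str]] | None" = None,
    ) -> "PanelDesign":
        """A panel whose haplotypes and backgrounds share one label set,
        with the identity map as the coevolved pairing (the usual situation
        when both genomes come from the same source strains)."""
        labels = tuple(labels)
        return cls(
            mito_labels=labels,
            nuc_labels=labels,
            coevolved={lab: lab for lab in labels},
            incompatible=frozenset(incompatible or ()),
        )


def drosophila_panel() -> PanelDesign:
    """The 9 x 9 worldwide *D. melanogaster* panel layout: strains A-I crossed
    fully, identity coevolved pairing, with the inviable F-nucleus x A-haplotype
    cell removed (80 analysable genotypes)."""
    labels = tuple("ABCDEFGHI")
    return PanelDesign.fully_crossed(labels, incompatible={("F", "A")})
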