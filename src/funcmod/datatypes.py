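"""Core value types shared across the pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered background population of gene identifiers.

    The universe defines N for every hypergeometric computation and the
    membership vectors behind kappa agreement.
    """

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("universe must contain at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("universe genes must be unique")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __iter__(self):
        return iter(self.genes)

    def index(self, gene: str) -> int:
        return self._index[gene]

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class OmicsGeneSet:
    """A named gene list from one omics source, optionally with per-gene logFC."""

    name: str
    genes: list[str]
    logfc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in set {self.name!r}")
        extra = set(self.logfc) - set(self.genes)
        if extra:
            raise ValueError(f"logFC given for non-member genes: {sorted(extra)[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)
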