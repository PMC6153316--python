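"""Gene-set collections and the GMT interchange format.

GMT is the tab-delimited format used by most enrichment tools: one set per
line, ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Any collection (KEGG
pathway export, MSigDB download, or the synthetic sets emitted by
:mod:`toxtempo.simulate`) can be used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import GmtParseError


@dataclass
class GeneSetCollection:
    """Named gene sets with (non-redundant) string memberships.

    ``sets`` maps name -> list of gene ids; ``descriptions`` maps name -> the
    free-text second GMT field.
    """

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name) -> bool:
        return name in self.sets

    def __getitem__(self, name) -> list:
        return self.sets[name]

    def add(self, name: str, genes, description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name: {name}")
        genes = list(dict.fromkeys(genes))
        if not genes:
            raise ValueError(f"gene set {name} is empty")
        self.sets[name] = genes
        self.descriptions[name] = description

    def restrict_to(self, measured_genes) -> "GeneSetCollection":
        """Drop members absent from *measured_genes*; drop sets left empty.

        Set sizes downstream (the K of the GFE score) always refer to the
        restricted collection.
        """
        keep = set(measured_genes)
        out = GeneSetCollection()
        for name, genes in self.sets.items():
            present = [g for g in genes if g in keep]
            if present:
                out.add(name, present, self.descriptions.get(name, ""))
        return out


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; malformed lines raise :class:`GmtParseError` with
    the 1-based line number."""
    out = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            try:
                out.add(name, genes, description)
            except ValueError as exc:
                raise GmtParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")
    return path
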