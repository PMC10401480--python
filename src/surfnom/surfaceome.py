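"""Surface-protein feature universe built from annotation sources.

The catalog is the union of several evidence sources for cell-surface
localization — typically a CD-nomenclature list, a mass-spectrometry
surfaceome atlas, and membrane-related GO terms (ion transmembrane
transport GO:0034220, transmembrane transport GO:0055085,
membrane GO:0016020) — with per-gene provenance.  Membership of a gene in
ANY source puts it in the catalog.

Identifiers are matched verbatim: no case folding and no alias
resolution, so the caller supplies harmonized gene symbols/ids.  GO
associations are read from a flat pre-propagated two-column table; no
ontology traversal is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import SurfnomError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSource:
    """One evidence source: an id and its deduplicated member gene set."""

    source_id: str
    members: frozenset = frozenset()

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass
class SurfaceCatalog:
    """Union of annotation sources with per-gene provenance tags."""

    provenance: dict = field(default_factory=dict)  # gene -> set of source ids

    def __contains__(self, gene: str) -> bool:
        return gene in self.provenance

    def __len__(self) -> int:
        return len(self.provenance)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.provenance)

    def sources_of(self, gene: str) -> frozenset:
        return frozenset(self.provenance.get(gene, ()))

    def filter(self, features: Iterable[str]) -> list:
        """Subset of *features* present in the catalog, input order kept."""
        return [f for f in features if f in self.provenance]


def load_gene_list(path, source_id: str | None = None) -> AnnotationSource:
    """Read a one-identifier-per-line gene list ('#' starts a comment)."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise SurfnomError(f"cannot read gene list {path}: {exc}") from exc
    members = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            members.add(line)
    if not members:
        logger.warning("gene list %s is empty", path)
    return AnnotationSource(source_id or path.stem, frozenset(members))


def load_go_associations(path, terms: Iterable[str]) -> list[AnnotationSource]:
    """One AnnotationSource per requested GO term from a gene<TAB>term table.

    The table carries pre-propagated annotations; a requested term absent
    from the file yields an empty source plus a warning.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise SurfnomError(f"cannot read GO associations {path}: {exc}") from exc
    by_term: dict[str, set] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 'gene<TAB>go_id', got {line!r}"
            )
        gene, term = (p.strip() for p in parts)
        by_term.setdefault(term, set()).add(gene)
    sources = []
    for term in terms:
        members = by_term.get(term)
        if members is None:
            logger.warning("GO term %s absent from %s; empty source", term, path)
            members = set()
        sources.append(AnnotationSource(term, frozenset(members)))
    return sources


def build_catalog(sources: Iterable[AnnotationSource]) -> SurfaceCatalog:
    """Union the sources into a catalog with provenance."""
    sources = list(sources)
    if not sources:
        raise ValidationError("at least one annotation source is required")
    provenance: dict[str, set] = {}
    for src in sources:
        for gene in src.members:
            provenance.setdefault(gene, set()).add(src.source_id)
    return SurfaceCatalog(provenance)


def warn_unannotated(catalog: SurfaceCatalog, features: Iterable[str]) -> list:
    """Log and return the features absent from every annotation source."""
    missing = [f for f in features if f not in catalog]
    if missing:
        logger.warning(
            "%d feature(s) in the expression data match no annotation source",
            len(missing),
        )
    return missing


def catalog_from_files(
    gene_lists: Mapping[str, str] | Iterable[str] = (),
    go_associations=None,
    go_terms: Iterable[str] = (),
) -> SurfaceCatalog:
    """Convenience builder from file paths.

    ``gene_lists`` is either a mapping source_id -> path or an iterable of
    paths (source id = file stem); ``go_associations`` plus ``go_terms``
    add one source per term.
    """
    sources: list[AnnotationSource] = []
    if isinstance(gene_lists, Mapping):
        for sid, p in gene_lists.items():
            sources.append(load_gene_list(p, sid))
    else:
        for p in gene_lists:
            sources.append(load_gene_list(p))
    if go_associations is not None and go_terms:
        sources.extend(load_go_associations(go_associations, list(go_terms)))
    return build_catalog(sources)
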