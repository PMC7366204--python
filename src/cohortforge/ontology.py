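"""Hierarchical concept catalogue with local-code mapping.

Concepts live in a forest addressed by ``/``-separated paths (e.g.
``Labs/Serum or Plasma/Serum Glucose``). Leaf nodes carry namespaced
codes (``LOINC:2345-7``); folder nodes carry none. Local codes from a
source system are attached as children of every node bearing their
standard code, so expanding a standard concept transparently matches the
local codes mapped to it — the mechanism that links facts coded with
site-local identifiers to the standard concept definition.

Paths are case-sensitive and matched exactly after whitespace trimming.
Segment text may not itself contain the separator.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Iterable

from .errors import LoadError, MappingError, NotFoundError

TSV_HEADER = ["path", "code", "name"]
MAPPING_HEADER = ["local_code", "standard_code"]


@dataclasses.dataclass
class ConceptNode:
    path: str
    code: str = ""
    name: str = ""
    parent_path: str = ""
    is_local: bool = False

    @property
    def segment(self) -> str:
        return self.path.rsplit("/", 1)[-1]


class ConceptHierarchy:
    """Forest of concept nodes indexed by path and by code."""

    def __init__(self):
        self.nodes: dict[str, ConceptNode] = {}
        self._children: dict[str, list[str]] = {}
        self._code_index: dict[str, list[str]] = {}

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, path: str) -> bool:
        return path in self.nodes

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConceptHierarchy):
            return NotImplemented
        mine = {p: (n.code, n.name, n.parent_path, n.is_local) for p, n in self.nodes.items()}
        theirs = {p: (n.code, n.name, n.parent_path, n.is_local) for p, n in other.nodes.items()}
        return mine == theirs

    # -- construction -------------------------------------------------------

    def add_node(
        self,
        path: str,
        code: str = "",
        name: str = "",
        is_local: bool = False,
        line: int | None = None,
    ) -> ConceptNode:
        """Insert a node, auto-creating missing folder ancestors.

        Re-adding an identical node is a no-op; the same path with a
        conflicting code is an error.
        """
        path = path.strip().strip("/")
        if not path:
            raise LoadError("empty concept path", line)
        code = (code or "").strip()
        name = (name or "").strip() or path.rsplit("/", 1)[-1]

        existing = self.nodes.get(path)
        if existing is not None:
            if existing.code and code and existing.code != code:
                raise LoadError(
                    f"duplicate path {path!r} with conflicting code "
                    f"({existing.code!r} vs {code!r})",
                    line,
                )
            if code and not existing.code:
                existing.code = code
                self._code_index.setdefault(code, []).append(path)
            if name and existing.name == existing.segment:
                existing.name = name
            return existing

        segments = path.split("/")
        parent = ""
        for seg in segments[:-1]:
            folder = f"{parent}/{seg}" if parent else seg
            if folder not in self.nodes:
                node = ConceptNode(path=folder, code="", name=seg, parent_path=parent)
                self.nodes[folder] = node
                self._children.setdefault(parent, []).append(folder)
            parent = folder

        node = ConceptNode(path=path, code=code, name=name, parent_path=parent, is_local=is_local)
        self.nodes[path] = node
        self._children.setdefault(parent, []).append(path)
        if code:
            self._code_index.setdefault(code, []).append(path)
        return node

    @classmethod
    def from_tsv(cls, source) -> "ConceptHierarchy":
        h = cls()
        h.merge_tsv(source)
        return h

    def merge_tsv(self, source) -> int:
        """Load ``path<TAB>code<TAB>name`` rows; returns rows consumed.

        Rows may arrive in any order; missing intermediate folders are
        auto-created, so the result is order-independent and idempotent.
        """
        close = False
        if isinstance(source, (str, bytes)):
            fh = open(source, encoding="utf-8")
            close = True
        else:
            fh = source
        try:
            header = fh.readline().rstrip("\n").split("\t")
            if [c.strip() for c in header] != TSV_HEADER:
                raise LoadError(
                    f"bad hierarchy header {header!r}; expected {TSV_HEADER!r}", 1
                )
            count = 0
            for lineno, raw in enumerate(fh, start=2):
                if not raw.strip():
                    continue
                cols = raw.rstrip("\n").split("\t")
                if len(cols) != 3:
                    raise LoadError(
                        f"expected 3 tab-separated columns, got {len(cols)}", lineno
                    )
                self.add_node(cols[0], cols[1], cols[2], line=lineno)
                count += 1
            return count
        finally:
            if close:
                fh.close()

    def write_tsv(self, target, separator: str = "/") -> int:
        """Write the hierarchy (folders included) sorted by path.

        ``separator="\\\\"`` emits the i2b2-native backslash path dialect.
        """
        close = False
        if isinstance(target, (str, bytes)):
            fh = open(target, "w", encoding="utf-8")
            close = True
        else:
            fh = target
        try:
            fh.write("\t".join(TSV_HEADER) + "\n")
            for path in sorted(self.nodes):
                node = self.nodes[path]
                out_path = path if separator == "/" else path.replace("/", separator)
                fh.write(f"{out_path}\t{node.code}\t{node.name}\n")
            return len(self.nodes)
        finally:
            if close:
                fh.close()

    # -- local-code mapping -------------------------------------------------

    def add_local_mapping(self, local_code: str, standard_code: str) -> list[str]:
        """Attach ``local_code`` as a child of every node bearing ``standard_code``.

        Returns the paths of the (created or pre-existing) local nodes.
        Idempotent: repeating an identical mapping changes nothing.
        """
        local_code = local_code.strip()
        standard_code = standard_code.strip()
        if ":" not in local_code:
            raise MappingError(f"local code {local_code!r} must be namespaced SYSTEM:code")
        parents = self._code_index.get(standard_code)
        if not parents:
            raise MappingError(f"unknown standard code {standard_code!r}")
        segment = local_code.split(":", 1)[1]
        created = []
        for parent in list(parents):
            child_path = f"{parent}/{segment}"
            existing = self.nodes.get(child_path)
            if existing is not None:
                if existing.code != local_code:
                    raise MappingError(
                        f"path {child_path!r} already holds code {existing.code!r}"
                    )
                created.append(child_path)
                continue
            self.add_node(child_path, code=local_code, name=local_code, is_local=True)
            created.append(child_path)
        return created

    def merge_mapping_tsv(self, source) -> int:
        """Load ``local_code<TAB>standard_code`` rows; returns mappings applied."""
        close = False
        if isinstance(source, (str, bytes)):
            fh = open(source, encoding="utf-8")
            close = True
        else:
            fh = source
        try:
            header = [c.strip() for c in fh.readline().rstrip("\n").split("\t")]
            if header != MAPPING_HEADER:
                raise LoadError(
                    f"bad mapping header {header!r}; expected {MAPPING_HEADER!r}", 1
                )
            count = 0
            for lineno, raw in enumerate(fh, start=2):
                if not raw.strip():
                    continue
                cols = raw.rstrip("\n").split("\t")
                if len(cols) != 2:
                    raise LoadError(
                        f"expected 2 tab-separated columns, got {len(cols)}", lineno
                    )
                self.add_local_mapping(cols[0], cols[1])
                count += 1
            return count
        finally:
            if close:
                fh.close()

    def code_map(self, direction: str = "local_to_standard") -> dict[str, str]:
        """Flat translation table derived from is_local links.

        ``local_to_standard`` maps each local code to its parent's standard
        code; ``standard_to_local`` is the reverse (first local child wins
        when several exist).
        """
        table: dict[str, str] = {}
        for node in self.nodes.values():
            if not node.is_local or not node.parent_path:
                continue
            parent = self.nodes[node.parent_path]
            if not parent.code:
                continue
            if direction == "local_to_standard":
                table[node.code] = parent.code
            elif direction == "standard_to_local":
                table.setdefault(parent.code, node.code)
            else:
                raise MappingError(f"unknown mapping direction {direction!r}")
        return table

    # -- retrieval ----------------------------------------------------------

    def children(self, path: str) -> list[ConceptNode]:
        return [self.nodes[p] for p in self._children.get(path, [])]

    def roots(self) -> list[ConceptNode]:
        return self.children("")

    def paths_for_code(self, code: str) -> list[str]:
        return list(self._code_index.get(code, []))

    def resolve(self, path_or_code: str) -> list[str]:
        """Resolve an argument to node paths: exact path first, then code."""
        arg = path_or_code.strip().strip("/")
        if arg in self.nodes:
            return [arg]
        paths = self._code_index.get(arg)
        if paths:
            return list(paths)
        raise NotFoundError(f"no concept path or code {path_or_code!r}")

    def expand(self, path_or_code: str) -> set[str]:
        """Codes of the resolved node(s) and all their descendants.

        Folder nodes contribute no code. Expanding a code present at
        multiple paths unions the expansions.
        """
        out: set[str] = set()
        stack = self.resolve(path_or_code)
        while stack:
            path = stack.pop()
            node = self.nodes[path]
            if node.code:
                out.add(node.code)
            stack.extend(self._children.get(path, []))
        return out

    def to_tsv_string(self, separator: str = "/") -> str:
        buf = io.StringIO()
        self.write_tsv(buf, separator=separator)
        return buf.getvalue()


def expand_many(hierarchy: "ConceptHierarchy | None", refs: Iterable[str]) -> set[str]:
    """Expand several path-or-code refs; unresolvable namespaced codes pass
    through literally (they are valid fact codes even when uncatalogued)."""
    out: set[str] = set()
    for ref in refs:
        if hierarchy is not None:
            try:
                out |= hierarchy.expand(ref)
                continue
            except NotFoundError:
                pass
        if ":" in ref:
            out.add(ref)
        else:
            raise NotFoundError(f"cannot resolve concept ref {ref!r}")
    return out
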