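"""Atom-selection mini-grammar.

Grammar (whitespace-tokenized, case-sensitive keywords)::

    expr     :=  or_expr
    or_expr  :=  and_expr ( "or" and_expr )*
    and_expr :=  unary ( "and" unary )*
    unary    :=  "not" unary  |  primary
    primary  :=  "(" expr ")"
               | "all" | "protein" | "water" | "solvent"
               | "backbone" | "sidechain"
               | "resid"   <int-or-range> ...
               | "resname" <name> ...
               | "name"    <name> ...
               | "chain"   <id> ...

``not`` complements within the selection universe (all atoms of the
structure by default, or an explicit ``universe`` AtomSet).  Backbone is
the fixed convention {N, CA, C, O, H, HA}; sidechain is any protein atom
outside it.  An expression that matches nothing raises SelectionError.
"""

from __future__ import annotations

from .errors import GrammarError, SelectionError
from .structure import AtomSet, Structure

__all__ = ["select", "BACKBONE_NAMES", "PROTEIN_RESNAMES", "WATER_RESNAMES"]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "H", "HA"})

PROTEIN_RESNAMES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL", "MSX", "MSE",
})

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP", "TIP3", "SOL", "SPC", "H2O"})

_KEYWORDS = {"and", "or", "not", "(", ")", "all", "protein", "water",
             "solvent", "backbone", "sidechain", "resid", "resname", "name",
             "chain"}


def _tokenize(spec: str) -> list[str]:
    return spec.replace("(", " ( ").replace(")", " ) ").split()


class _Parser:
    def __init__(self, tokens: list[str], structure: Structure, universe: set[int]):
        self.toks = tokens
        self.pos = 0
        self.s = structure
        self.universe = universe

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GrammarError("unexpected end of selection expression")
        self.pos += 1
        return tok

    # --- grammar -----------------------------------------------------
    def expr(self) -> set[int]:
        result = self.and_expr()
        while self.peek() == "or":
            self.take()
            result = result | self.and_expr()
        return result

    def and_expr(self) -> set[int]:
        result = self.unary()
        while self.peek() == "and":
            self.take()
            result = result & self.unary()
        return result

    def unary(self) -> set[int]:
        if self.peek() == "not":
            self.take()
            return self.universe - self.unary()
        return self.primary()

    def primary(self) -> set[int]:
        tok = self.take()
        if tok == "(":
            inner = self.expr()
            if self.take() != ")":
                raise GrammarError("unbalanced parenthesis")
            return inner
        if tok == "all":
            return set(self.universe)
        if tok == "protein":
            return self._match(lambda a: a.residue_name in PROTEIN_RESNAMES)
        if tok in ("water", "solvent"):
            return self._match(lambda a: a.residue_name in WATER_RESNAMES)
        if tok == "backbone":
            return self._match(lambda a: a.residue_name in PROTEIN_RESNAMES
                               and a.name in BACKBONE_NAMES)
        if tok == "sidechain":
            return self._match(lambda a: a.residue_name in PROTEIN_RESNAMES
                               and a.name not in BACKBONE_NAMES)
        if tok == "resid":
            ids = self._collect_ids()
            return self._match(lambda a: a.residue_id in ids)
        if tok == "resname":
            names = set(self._collect_names())
            return self._match(lambda a: a.residue_name in names)
        if tok == "name":
            names = set(self._collect_names())
            return self._match(lambda a: a.name in names)
        if tok == "chain":
            names = set(self._collect_names())
            return self._match(lambda a: a.chain_id in names)
        raise GrammarError(f"unknown selection keyword {tok!r}")

    # --- helpers -----------------------------------------------------
    def _collect_names(self) -> list[str]:
        names = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            names.append(self.take())
        if not names:
            raise GrammarError("keyword requires at least one argument")
        return names

    def _collect_ids(self) -> set[int]:
        ids: set[int] = set()
        for tok in self._collect_names():
            try:
                if ":" in tok:
                    lo, hi = tok.split(":")
                    ids.update(range(int(lo), int(hi) + 1))
                else:
                    ids.add(int(tok))
            except ValueError as exc:
                raise GrammarError(f"bad residue id {tok!r}") from exc
        return ids

    def _match(self, predicate) -> set[int]:
        return {i for i in self.universe if predicate(self.s.atoms[i])}


def select(structure: Structure, spec: str,
           universe: AtomSet | None = None) -> AtomSet:
    """Evaluate a selection expression on a structure.

    Parameters
    ----------
    structure:
        The structure to select from.
    spec:
        Expression in the mini-grammar documented in this module.
    universe:
        Optional AtomSet restricting both matching and ``not``
        complementation; defaults to all atoms.
    """
    uni = (set(universe.indices) if universe is not None
           else set(range(len(structure.atoms))))
    parser = _Parser(_tokenize(spec), structure, uni)
    result = parser.expr()
    if parser.peek() is not None:
        raise GrammarError(f"trailing tokens at {parser.peek()!r}")
    if not result:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return AtomSet(frozenset(result), label=spec)
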