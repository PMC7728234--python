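"""Reading and validating genome-scale metabolic models and annotation tables.

Two model dialects are supported: BiGG-style JSON (read and written directly,
so that a load -> serialize -> load round trip preserves the stoichiometric
matrix and bounds bit-exactly) and SBML Level 3 with the FBC package (parsed
through cobrapy/libsbml).  Both are converted into the same numerical
:class:`MetabolicModel` structure that all other modules consume.

Sign convention: for an exchange reaction, flux < 0 is uptake and flux > 0 is
secretion.  Reversibility is encoded solely through a negative lower bound,
never by duplicating reactions; flux splitting happens only inside optimizers.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import ContractError, ModelFormatError

ROLE_INTERNAL = "internal"
ROLE_EXCHANGE = "exchange"
ROLE_BIOMASS = "biomass"

#: id prefixes marking boundary pseudo-reactions whose column may be empty
#: (demand/sink) or single-metabolite (exchange)
_BOUNDARY_PREFIXES = ("EX_", "DM_", "SK_")


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRNode:
    """Node of a boolean gene-protein-reaction rule tree.

    ``kind`` is one of ``"and"``, ``"or"``, ``"gene"``, ``"empty"``.  The leaf
    set (:attr:`genes`) is what downstream gene mapping consumes; the tree
    itself is retained so AND (enzyme complex) vs OR (isozyme) structure is
    not lost.
    """

    kind: str
    gene: str | None = None
    children: tuple["GPRNode", ...] = ()

    @property
    def genes(self) -> frozenset[str]:
        if self.kind == "gene":
            return frozenset([self.gene])
        out: set[str] = set()
        for child in self.children:
            out |= child.genes
        return frozenset(out)

    @property
    def is_empty(self) -> bool:
        return self.kind == "empty"


_TOKEN_RE = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gpr(rule_text: str) -> GPRNode:
    """Parse a boolean gene rule ("b0001 and (b0002 or b0003)") into a tree.

    Empty or whitespace-only text yields the empty rule.  Unbalanced
    parentheses or dangling operators raise :class:`ModelFormatError`.
    Grammar (recursive descent, OR binds loosest):

        expr    := term ("or" term)*
        term    := factor ("and" factor)*
        factor  := gene | "(" expr ")"
    """
    tokens = _TOKEN_RE.findall(rule_text or "")
    if not tokens:
        return GPRNode("empty")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> GPRNode:
        node = parse_term()
        parts = [node]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(parse_term())
        if len(parts) == 1:
            return parts[0]
        return GPRNode("or", children=tuple(parts))

    def parse_term() -> GPRNode:
        parts = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(parse_factor())
        if len(parts) == 1:
            return parts[0]
        return GPRNode("and", children=tuple(parts))

    def parse_factor() -> GPRNode:
        tok = peek()
        if tok is None:
            raise ModelFormatError(f"GPR rule ended unexpectedly: {rule_text!r}")
        if tok == "(":
            take()
            node = parse_expr()
            if peek() != ")":
                raise ModelFormatError(f"unbalanced parentheses in GPR rule: {rule_text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelFormatError(f"unexpected token {tok!r} in GPR rule: {rule_text!r}")
        take()
        return GPRNode("gene", gene=tok)

    tree = parse_expr()
    if pos != len(tokens):
        raise ModelFormatError(f"trailing tokens in GPR rule: {rule_text!r}")
    return tree


def gpr_to_string(node: GPRNode) -> str:
    """Render a rule tree back into the standard textual form."""
    if node.kind == "empty":
        return ""
    if node.kind == "gene":
        return node.gene
    sep = f" {node.kind} "
    parts = []
    for child in node.children:
        text = gpr_to_string(child)
        if child.kind in ("and", "or") and child.kind != node.kind:
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)


# ---------------------------------------------------------------------------
# MetabolicModel
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """Numerical view of a genome-scale metabolic model.

    S is the m x r stoichiometric matrix over ``metabolite_ids`` (rows) and
    ``reaction_ids`` (columns); ``lb``/``ub`` are flux bounds in
    mmol gDW^-1 h^-1 (the biomass reaction in h^-1).  Each reaction carries a
    role (internal / exchange / biomass) and an optional GPR rule.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    reaction_roles: list[str]
    biomass_reaction_id: str
    gpr: list[GPRNode] = field(default_factory=list)
    subsystems: list[str] = field(default_factory=list)
    metabolite_names: list[str] = field(default_factory=list)
    reaction_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.S = sp.csc_matrix(self.S)
        if not self.gpr:
            self.gpr = [GPRNode("empty")] * self.n_reactions
        if not self.subsystems:
            self.subsystems = [""] * self.n_reactions
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}

    # -- basic accessors ----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def rxn_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise ContractError(f"unknown reaction id {reaction_id!r}") from None

    def met_index(self, metabolite_id: str) -> int:
        try:
            return self._met_index[metabolite_id]
        except KeyError:
            raise ContractError(f"unknown metabolite id {metabolite_id!r}") from None

    @property
    def biomass_index(self) -> int:
        return self.rxn_index(self.biomass_reaction_id)

    def exchange_reactions(self) -> list[str]:
        return [r for r, role in zip(self.reaction_ids, self.reaction_roles)
                if role == ROLE_EXCHANGE]

    def internal_reactions(self) -> list[str]:
        return [r for r, role in zip(self.reaction_ids, self.reaction_roles)
                if role == ROLE_INTERNAL]

    def internal_indices(self) -> np.ndarray:
        return np.array([i for i, role in enumerate(self.reaction_roles)
                         if role == ROLE_INTERNAL], dtype=int)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rule in self.gpr:
            out |= rule.genes
        return frozenset(out)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ModelFormatError on violation."""
        m, r = self.S.shape
        if m != self.n_metabolites or r != self.n_reactions:
            raise ModelFormatError(
                f"S has shape {self.S.shape}, expected "
                f"({self.n_metabolites}, {self.n_reactions})")
        if np.any(self.lb > self.ub):
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ModelFormatError(f"lb > ub for reaction {bad!r}")
        counts = np.diff(self.S.indptr)  # nonzeros per column (csc)
        for j in np.flatnonzero(counts == 0):
            rid = self.reaction_ids[j]
            if not rid.startswith(("DM_", "SK_")):
                raise ModelFormatError(
                    f"reaction {rid!r} has an all-zero stoichiometry column "
                    "and is not a flagged demand/sink reaction")
        roles = np.asarray(self.reaction_roles)
        if int(np.sum(roles == ROLE_BIOMASS)) != 1:
            raise ModelFormatError("model must have exactly one biomass reaction")
        if self.reaction_roles[self.biomass_index] != ROLE_BIOMASS:
            raise ModelFormatError(
                f"biomass_reaction_id {self.biomass_reaction_id!r} is not the "
                "reaction carrying the biomass role")
        for j in np.flatnonzero(roles == ROLE_EXCHANGE):
            if counts[j] != 1:
                raise ModelFormatError(
                    f"exchange reaction {self.reaction_ids[j]!r} touches "
                    f"{counts[j]} metabolites, expected exactly 1")

    def copy_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lb.copy(), self.ub.copy()


def detect_exchanges(model: MetabolicModel) -> list[str]:
    """Brute-force scan for single-metabolite boundary columns of S.

    Used as the reference for exchange-role assignment tests; role assignment
    during loading must agree with this scan for boundary-prefixed reactions.
    """
    counts = np.diff(model.S.indptr)
    return [rid for j, rid in enumerate(model.reaction_ids)
            if counts[j] == 1 and rid.startswith(_BOUNDARY_PREFIXES)]


# ---------------------------------------------------------------------------
# Loading / serialization
# ---------------------------------------------------------------------------

def _assign_roles(reaction_ids, stoich_counts, single_metabolite,
                  objective_ids) -> tuple[list[str], str]:
    roles = []
    biomass_id = None
    for rid, nmet, single in zip(reaction_ids, stoich_counts, single_metabolite):
        if rid in objective_ids or "biomass" in rid.lower():
            roles.append(ROLE_BIOMASS)
            if biomass_id is None:
                biomass_id = rid
        elif single and rid.startswith(_BOUNDARY_PREFIXES):
            roles.append(ROLE_EXCHANGE)
        elif nmet == 0 and rid.startswith(("DM_", "SK_")):
            roles.append(ROLE_EXCHANGE)
        else:
            roles.append(ROLE_INTERNAL)
    if biomass_id is None:
        raise ModelFormatError("no biomass reaction found (no objective "
                               "coefficient and no id containing 'biomass')")
    # if several ids matched (e.g. core + wildtype biomass in iJO1366), keep
    # the objective one as biomass and demote the rest to internal
    n_bio = roles.count(ROLE_BIOMASS)
    if n_bio > 1:
        preferred = next((rid for rid in objective_ids if rid in reaction_ids), biomass_id)
        for i, rid in enumerate(reaction_ids):
            if roles[i] == ROLE_BIOMASS and rid != preferred:
                roles[i] = ROLE_INTERNAL
        biomass_id = preferred
    return roles, biomass_id


def _load_bigg_json(path: Path) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing top-level {key!r} list")
    met_ids = [m["id"] for m in doc["metabolites"]]
    met_names = [m.get("name", "") for m in doc["metabolites"]]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rxn_ids, lbs, ubs, gprs, subsystems, rxn_names = [], [], [], [], [], []
    rows, cols, vals = [], [], []
    objective_ids = set()
    for j, rxn in enumerate(doc["reactions"]):
        try:
            rxn_ids.append(rxn["id"])
            lbs.append(float(rxn["lower_bound"]))
            ubs.append(float(rxn["upper_bound"]))
        except KeyError as exc:
            raise ModelFormatError(
                f"{path}: reaction #{j} missing required field {exc}") from exc
        for met, coef in rxn.get("metabolites", {}).items():
            if met not in met_pos:
                raise ModelFormatError(
                    f"{path}: reaction {rxn['id']!r} references unknown "
                    f"metabolite {met!r}")
            rows.append(met_pos[met])
            cols.append(j)
            vals.append(float(coef))
        gprs.append(parse_gpr(rxn.get("gene_reaction_rule", "")))
        subsystems.append(rxn.get("subsystem", "") or "")
        rxn_names.append(rxn.get("name", "") or "")
        if float(rxn.get("objective_coefficient", 0.0)) != 0.0:
            objective_ids.add(rxn["id"])
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    counts = np.diff(S.indptr)
    roles, biomass_id = _assign_roles(
        rxn_ids, counts, counts == 1, objective_ids)
    model = MetabolicModel(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        lb=np.array(lbs), ub=np.array(ubs), reaction_roles=roles,
        biomass_reaction_id=biomass_id, gpr=gprs, subsystems=subsystems,
        metabolite_names=met_names, reaction_names=rxn_names)
    model.validate()
    return model


def _load_sbml_fbc(path: Path) -> MetabolicModel:
    # cobrapy wraps libsbml and handles the FBC package; unknown annotations
    # are ignored by design
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several parse error types
        raise ModelFormatError(f"{path}: SBML parse failure: {exc}") from exc
    met_ids = [m.id for m in cm.metabolites]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rxn_ids = [r.id for r in cm.reactions]
    rows, cols, vals = [], [], []
    lbs, ubs, gprs, subsystems, rxn_names = [], [], [], [], []
    objective_ids = {r.id for r in cm.reactions
                     if r.objective_coefficient not in (0, 0.0)}
    for j, rxn in enumerate(cm.reactions):
        lbs.append(float(rxn.lower_bound))
        ubs.append(float(rxn.upper_bound))
        for met, coef in rxn.metabolites.items():
            rows.append(met_pos[met.id])
            cols.append(j)
            vals.append(float(coef))
        gprs.append(parse_gpr(rxn.gene_reaction_rule or ""))
        subsystems.append(rxn.subsystem or "")
        rxn_names.append(rxn.name or "")
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    counts = np.diff(S.indptr)
    roles, biomass_id = _assign_roles(rxn_ids, counts, counts == 1, objective_ids)
    model = MetabolicModel(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        lb=np.array(lbs), ub=np.array(ubs), reaction_roles=roles,
        biomass_reaction_id=biomass_id, gpr=gprs, subsystems=subsystems,
        metabolite_names=[m.name or "" for m in cm.metabolites],
        reaction_names=rxn_names)
    model.validate()
    return model


def load_model(path: str | Path, dialect: str = "bigg_json") -> MetabolicModel:
    """Load a metabolic model; ``dialect`` is ``"bigg_json"`` or ``"sbml_fbc"``.

    Reaction and metabolite order is the file order.  The returned model has
    been validated against all structural invariants.
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    if dialect == "bigg_json":
        return _load_bigg_json(path)
    if dialect == "sbml_fbc":
        return _load_sbml_fbc(path)
    raise ContractError(f"unknown model dialect {dialect!r}")


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Serialize a model to the BiGG-style JSON dialect.

    Round trip is a fixed point: reloading preserves S, lb and ub bit-exactly
    (floats are emitted with repr precision).
    """
    doc = model_to_dict(model)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def model_to_dict(model: MetabolicModel) -> dict:
    S = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = S.getcol(j).tocoo()
        mets = {model.metabolite_ids[i]: float(v) for i, v in zip(col.row, col.data)}
        entry = {
            "id": rid,
            "name": model.reaction_names[j] if model.reaction_names else "",
            "metabolites": mets,
            "lower_bound": float(model.lb[j]),
            "upper_bound": float(model.ub[j]),
            "gene_reaction_rule": gpr_to_string(model.gpr[j]),
            "subsystem": model.subsystems[j],
        }
        if rid == model.biomass_reaction_id:
            entry["objective_coefficient"] = 1.0
        reactions.append(entry)
    metabolites = []
    for i, mid in enumerate(model.metabolite_ids):
        metabolites.append({
            "id": mid,
            "name": model.metabolite_names[i] if model.metabolite_names else "",
            "compartment": mid.rsplit("_", 1)[-1] if "_" in mid else "c",
        })
    return {"metabolites": metabolites, "reactions": reactions, "genes": [
        {"id": g} for g in sorted(model.genes())], "id": "crossfeed_model",
        "version": "1"}


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTables:
    """Gene-level annotations: operon membership, regulon membership, and an
    optional observed expression-change table (gene x strain -> up/down/unchanged).

    Unknown genes are permitted everywhere; lookups simply return nothing.
    """

    gene_to_operon: dict[str, str] = field(default_factory=dict)
    gene_to_regulons: dict[str, frozenset[str]] = field(default_factory=dict)
    expression: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.gene_to_operon and not self.gene_to_regulons

    def operon(self, gene: str) -> str | None:
        return self.gene_to_operon.get(gene)

    def regulons(self, gene: str) -> frozenset[str]:
        return self.gene_to_regulons.get(gene, frozenset())


_EXPRESSION_LEVELS = {"up", "down", "unchanged"}


def _read_tsv(path: Path, n_cols: int, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ModelFormatError(f"{path}: cannot parse {what} TSV: {exc}") from exc
    if df.shape[1] < n_cols:
        raise ModelFormatError(
            f"{path}: {what} table needs at least {n_cols} columns, "
            f"found {df.shape[1]}")
    bad = df.iloc[:, :n_cols].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise ModelFormatError(f"{path}: malformed {what} row at line {row}")
    return df


def load_annotations(
    operon_path: str | Path | None = None,
    regulon_path: str | Path | None = None,
    expression_path: str | Path | None = None,
) -> AnnotationTables:
    """Load TSV annotation tables (header row required; UTF-8).

    operon table: columns (gene, operon); duplicate gene rows are an error.
    regulon table: columns (gene, regulon); repeated genes accumulate.
    expression table: columns (gene, strain, change) with change in
    {up, down, unchanged}.
    """
    tables = AnnotationTables()
    if operon_path is not None:
        df = _read_tsv(Path(operon_path), 2, "gene->operon")
        genes = df.iloc[:, 0]
        if genes.duplicated().any():
            dup = genes[genes.duplicated()].iloc[0]
            raise ModelFormatError(
                f"{operon_path}: duplicate gene {dup!r} in operon table")
        tables.gene_to_operon = dict(zip(genes, df.iloc[:, 1]))
    if regulon_path is not None:
        df = _read_tsv(Path(regulon_path), 2, "gene->regulon")
        acc: dict[str, set[str]] = {}
        for gene, regulon in zip(df.iloc[:, 0], df.iloc[:, 1]):
            acc.setdefault(gene, set()).add(regulon)
        tables.gene_to_regulons = {g: frozenset(s) for g, s in acc.items()}
    if expression_path is not None:
        df = _read_tsv(Path(expression_path), 3, "expression")
        for k, (gene, strain, change) in enumerate(
                zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])):
            if change not in _EXPRESSION_LEVELS:
                raise ModelFormatError(
                    f"{expression_path}: line {k + 2}: expression change "
                    f"{change!r} not in {sorted(_EXPRESSION_LEVELS)}")
            tables.expression[(gene, strain)] = change
    return tables
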