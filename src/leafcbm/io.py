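"""Model I/O: a human-editable TSV dialect and SBML Level 3 (FBC).

TSV dialect
-----------
One UTF-8 file, tab-separated, organised in sections opened by a ``!`` line::

    !model  <id>    <name>  <external_compartment>
    !compartments
    id      name
    !metabolites
    id      name    compartment     formula boundary        annotations
    !reactions
    id      name    equation        lb      ub      gpr     pathway ec      annotations
    !objective
    reaction        coefficient

Equations use ``->`` (irreversible) or ``<->`` (reversible) arrows with
explicit coefficients (``2 pga_h``).  Stoichiometric coefficients and bounds
are serialized with full float precision so that a TSV round trip is
bit-exact.  ``annotations`` is a ``key=value;key=value`` list.

SBML goes through COBRApy (python-libsbml underneath); pathway tags map to
reaction subsystems (SBML groups), roles are carried in annotation notes.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from .model import (
    DEFAULT_BOUND,
    Diagnostic,
    Metabolite,
    Reaction,
    StoichiometricModel,
    validate_model,
)

__all__ = [
    "load_model",
    "save_model",
    "read_tsv_model",
    "write_tsv_model",
    "read_sbml_model",
    "write_sbml_model",
    "parse_equation",
    "format_equation",
    "to_cobra",
    "from_cobra",
    "ModelFormatError",
    "ModelValidationError",
]


class ModelFormatError(ValueError):
    """A file could not be parsed in the requested format."""


class ModelValidationError(ValueError):
    """A parsed model violates structural invariants."""

    def __init__(self, diagnostics: List[Diagnostic]):
        self.diagnostics = diagnostics
        lines = "; ".join(f"{d.entity}: {d.rule} ({d.message})" for d in diagnostics)
        super().__init__(f"model failed validation: {lines}")


# ---------------------------------------------------------------------------
# equation strings
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$")


def parse_equation(equation: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``"a + 2 b -> c"`` into a stoichiometry map.

    Returns ``(stoichiometry, reversible_arrow)``.
    """
    if "<->" in equation:
        lhs, rhs = equation.split("<->")
        reversible = True
    elif "->" in equation:
        lhs, rhs = equation.split("->")
        reversible = False
    else:
        raise ModelFormatError(f"no arrow in equation {equation!r}")

    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if m is None:
                raise ModelFormatError(f"malformed term {term!r} in {equation!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return stoich, reversible


def format_equation(rxn: Reaction, precise: bool = True) -> str:
    """Inverse of :func:`parse_equation`; ``precise`` uses repr floats."""

    def fmt(coef: float) -> str:
        if coef == 1.0:
            return ""
        return (repr(coef) if precise else f"{coef:g}") + " "

    subs = [(m, -c) for m, c in rxn.stoichiometry.items() if c < 0]
    prods = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<->" if rxn.lower_bound < 0 else "->"
    left = " + ".join(f"{fmt(c)}{m}" for m, c in sorted(subs))
    right = " + ".join(f"{fmt(c)}{m}" for m, c in sorted(prods))
    return f"{left} {arrow} {right}".strip()


def _fmt_annotations(ann: Dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(ann.items()))


def _parse_annotations(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for item in text.split(";"):
        item = item.strip()
        if item:
            if "=" not in item:
                raise ModelFormatError(f"malformed annotation {item!r}")
            k, v = item.split("=", 1)
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv_model(model: StoichiometricModel, path: Union[str, Path]) -> None:
    lines: List[str] = []
    lines.append(f"!model\t{model.id}\t{model.name}\t{model.external_compartment}")
    lines.append("!compartments")
    lines.append("id\tname")
    for cid, cname in model.compartments.items():
        lines.append(f"{cid}\t{cname}")
    lines.append("!metabolites")
    lines.append("id\tname\tcompartment\tformula\tboundary\tannotations")
    for met in model.metabolites.values():
        lines.append(
            "\t".join(
                [
                    met.id,
                    met.name,
                    met.compartment,
                    met.formula or "",
                    "1" if met.is_boundary else "0",
                    _fmt_annotations(met.annotations),
                ]
            )
        )
    lines.append("!reactions")
    lines.append("id\tname\tequation\tlb\tub\tgpr\tpathway\tec\tannotations")
    for rxn in model.reactions.values():
        lines.append(
            "\t".join(
                [
                    rxn.id,
                    rxn.name,
                    format_equation(rxn),
                    repr(rxn.lower_bound),
                    repr(rxn.upper_bound),
                    rxn.gpr,
                    rxn.pathway,
                    rxn.ec_number,
                    _fmt_annotations(rxn.annotations),
                ]
            )
        )
    lines.append("!objective")
    lines.append("reaction\tcoefficient")
    for rid, coef in model.objective.items():
        lines.append(f"{rid}\t{repr(coef)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tsv_model(path: Union[str, Path]) -> StoichiometricModel:
    path = Path(path)
    model = StoichiometricModel(id=path.stem)
    section: Optional[str] = None
    header_seen = False
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        if raw.startswith("!"):
            fields = raw.split("\t")
            tag = fields[0][1:]
            if tag == "model":
                model.id = fields[1] if len(fields) > 1 else model.id
                model.name = fields[2] if len(fields) > 2 else model.id
                if len(fields) > 3 and fields[3]:
                    model.external_compartment = fields[3]
                section = None
            elif tag in {"compartments", "metabolites", "reactions", "objective"}:
                section = tag
                header_seen = False
            else:
                raise ModelFormatError(f"line {lineno}: unknown section {tag!r}")
            continue
        if section is None:
            raise ModelFormatError(f"line {lineno}: data outside any section")
        if not header_seen:
            header_seen = True  # column header row
            continue
        cols = raw.split("\t")
        try:
            if section == "compartments":
                model.add_compartment(cols[0], cols[1] if len(cols) > 1 else "")
            elif section == "metabolites":
                cols += [""] * (6 - len(cols))
                model.add_metabolite(
                    Metabolite(
                        id=cols[0],
                        name=cols[1],
                        compartment=cols[2],
                        formula=cols[3] or None,
                        is_boundary=cols[4] == "1",
                        annotations=_parse_annotations(cols[5]),
                    )
                )
            elif section == "reactions":
                cols += [""] * (9 - len(cols))
                stoich, reversible = parse_equation(cols[2])
                lb = float(cols[3]) if cols[3] else (-DEFAULT_BOUND if reversible else 0.0)
                ub = float(cols[4]) if cols[4] else DEFAULT_BOUND
                model.add_reaction(
                    Reaction(
                        id=cols[0],
                        name=cols[1],
                        stoichiometry=stoich,
                        lower_bound=lb,
                        upper_bound=ub,
                        gpr=cols[5],
                        pathway=cols[6],
                        ec_number=cols[7],
                        annotations=_parse_annotations(cols[8]),
                    )
                )
            elif section == "objective":
                model.objective[cols[0]] = float(cols[1])
        except Exception as exc:  # re-raise with position info
            raise ModelFormatError(f"line {lineno} ({section}): {exc}") from exc
    return model


# ---------------------------------------------------------------------------
# COBRApy conversion and SBML
# ---------------------------------------------------------------------------

def to_cobra(model: StoichiometricModel):
    """Convert to a :class:`cobra.Model` (for solving or SBML export)."""
    import cobra

    cm = cobra.Model(model.id, name=model.name)
    cm.compartments = dict(model.compartments)
    mets = {}
    for met in model.metabolites.values():
        m = cobra.Metabolite(
            met.id,
            name=met.name,
            compartment=met.compartment,
            formula=met.formula,
        )
        if met.role:
            m.notes["role"] = met.role
        mets[met.id] = m
    rxns = []
    for rxn in model.reactions.values():
        r = cobra.Reaction(
            rxn.id,
            name=rxn.name,
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        r.notes["pathway"] = rxn.pathway
        if rxn.role:
            r.notes["role"] = rxn.role
        if rxn.pathway:
            r.subsystem = rxn.pathway
        rxns.append(r)
    cm.add_reactions(rxns)
    cm.add_metabolites(list(mets.values()))
    for rxn in model.reactions.values():
        cr = cm.reactions.get_by_id(rxn.id)
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.gpr:
            cr.gene_reaction_rule = rxn.gpr
    if model.objective:
        cm.objective = {
            cm.reactions.get_by_id(rid): coef for rid, coef in model.objective.items()
        }
    return cm


def from_cobra(cm) -> StoichiometricModel:
    """Convert a :class:`cobra.Model` into the plain domain model."""
    from cobra.util.solver import linear_reaction_coefficients

    model = StoichiometricModel(id=cm.id or "model", name=cm.name or "")
    for cid, cname in cm.compartments.items():
        model.add_compartment(cid, cname)
    for m in cm.metabolites:
        if m.compartment and m.compartment not in model.compartments:
            model.add_compartment(m.compartment)
        ann = {}
        if isinstance(m.notes, dict) and m.notes.get("role"):
            ann["role"] = str(m.notes["role"])
        model.add_metabolite(
            Metabolite(
                id=m.id,
                name=m.name or "",
                compartment=m.compartment or "",
                formula=m.formula or None,
                annotations=ann,
            )
        )
    for r in cm.reactions:
        ann = {}
        if isinstance(r.notes, dict) and r.notes.get("role"):
            ann["role"] = str(r.notes["role"])
        pathway = ""
        if isinstance(r.notes, dict) and r.notes.get("pathway"):
            pathway = str(r.notes["pathway"])
        elif r.subsystem:
            pathway = r.subsystem
        elif r.boundary:
            pathway = "exchange"
        model.add_reaction(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gpr=r.gene_reaction_rule or "",
                pathway=pathway,
                ec_number="",
                annotations=ann,
            )
        )
    for rxn, coef in linear_reaction_coefficients(cm).items():
        model.objective[rxn.id] = coef
    return model


def write_sbml_model(model: StoichiometricModel, path: Union[str, Path]) -> None:
    import cobra

    cobra.io.write_sbml_model(to_cobra(model), str(path))


def read_sbml_model(path: Union[str, Path]) -> StoichiometricModel:
    import cobra

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"SBML parse failure for {path}: {exc}") from exc
    return from_cobra(cm)


# ---------------------------------------------------------------------------
# front door
# ---------------------------------------------------------------------------

def load_model(
    path: Union[str, Path],
    format: Optional[str] = None,
    validate: bool = True,
) -> StoichiometricModel:
    """Load a model from TSV or SBML.

    ``format`` is inferred from the suffix when omitted (``.tsv`` vs
    ``.xml``/``.sbml``).  With ``validate=True`` (default) structural
    invariants are enforced and a :class:`ModelValidationError` listing the
    offending entities is raised on failure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("tsv" if path.suffix == ".tsv" else "sbml")
    if fmt == "tsv":
        model = read_tsv_model(path)
    elif fmt == "sbml":
        model = read_sbml_model(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if validate:
        diags = [d for d in validate_model(model) if d.rule != "element-balance"]
        if diags:
            raise ModelValidationError(diags)
    return model


def save_model(model: StoichiometricModel, path: Union[str, Path],
               format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or ("tsv" if path.suffix == ".tsv" else "sbml")
    if fmt == "tsv":
        write_tsv_model(model, path)
    elif fmt == "sbml":
        write_sbml_model(model, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
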