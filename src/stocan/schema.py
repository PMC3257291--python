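"""Native structured-text model schema, plus optional SBML level-3 import.

The native format is line oriented::

    model birth_death
    kind markov-jump

    species
      X = 5

    parameters
      k_s = 2.0
      k_d = 0.4

    reactions
      synthesis: -> X ; k_s
      degradation: X -> ; k_d * X

Species lines are ``id = initial_amount`` with an optional trailing
``boundary`` flag.  Reaction lines are ``id: reactants -> products ; rate``
where each side is a ``+``-separated list of ``[coefficient] species`` terms.
Langevin models add a ``diffusion`` section holding the rows of the constant
diffusion matrix over dynamic species (declaration order).

``#`` starts a comment anywhere on a line.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .errors import SchemaError
from .network import Parameter, Reaction, ReactionNetwork, Species

__all__ = ["parse_model_text", "load_model", "serialize_model", "import_sbml"]

_SECTIONS = {"species", "parameters", "reactions", "diffusion"}


def _split_terms(side: str, where: str):
    side = side.strip()
    out = {}
    if not side:
        return out
    for term in side.split("+"):
        term = term.strip()
        m = re.fullmatch(r"(?:(\d+)\s+)?([A-Za-z_]\w*)", term)
        if not m:
            raise SchemaError(f"{where}: cannot parse stoichiometric term {term!r}")
        coeff = int(m.group(1) or 1)
        sid = m.group(2)
        out[sid] = out.get(sid, 0) + coeff
    return out


def parse_model_text(text: str) -> ReactionNetwork:
    name = "model"
    kind = "markov-jump"
    species: list[Species] = []
    parameters: list[Parameter] = []
    reactions: list[Reaction] = []
    diffusion_rows: list[list[float]] = []
    section = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        where = f"line {lineno}"
        low = line.lower()
        if low.startswith("model "):
            name = line.split(None, 1)[1].strip()
            continue
        if low.startswith("kind "):
            kind = line.split(None, 1)[1].strip()
            continue
        if low in _SECTIONS:
            section = low
            continue
        if section == "species":
            m = re.fullmatch(r"([A-Za-z_]\w*)\s*=\s*([^\s]+)(\s+boundary)?", line)
            if not m:
                raise SchemaError(f"{where}: malformed species line {line!r}")
            try:
                amount = float(m.group(2))
            except ValueError:
                raise SchemaError(f"{where}: bad species amount {m.group(2)!r}") from None
            species.append(Species(m.group(1), amount, bool(m.group(3))))
        elif section == "parameters":
            m = re.fullmatch(r"([A-Za-z_]\w*)\s*=\s*([^\s]+)", line)
            if not m:
                raise SchemaError(f"{where}: malformed parameter line {line!r}")
            try:
                value = float(m.group(2))
            except ValueError:
                raise SchemaError(f"{where}: bad parameter value {m.group(2)!r}") from None
            parameters.append(Parameter(m.group(1), value))
        elif section == "reactions":
            m = re.fullmatch(r"([A-Za-z_]\w*)\s*:\s*(.*?)->(.*?);(.*)", line)
            if not m:
                raise SchemaError(f"{where}: malformed reaction line {line!r}")
            rid = m.group(1)
            reactants = _split_terms(m.group(2), where)
            products = _split_terms(m.group(3), where)
            stoich: dict[str, int] = {}
            for sid, c in reactants.items():
                stoich[sid] = stoich.get(sid, 0) - c
            for sid, c in products.items():
                stoich[sid] = stoich.get(sid, 0) + c
            stoich = {k: v for k, v in stoich.items() if v != 0}
            if not stoich:
                raise SchemaError(f"{where}: reaction {rid!r} has zero net stoichiometry")
            reactions.append(Reaction(rid, stoich, m.group(4).strip()))
        elif section == "diffusion":
            try:
                diffusion_rows.append([float(tok) for tok in line.split()])
            except ValueError:
                raise SchemaError(f"{where}: bad diffusion row {line!r}") from None
        else:
            raise SchemaError(f"{where}: content outside any section: {line!r}")

    diffusion = np.array(diffusion_rows, dtype=float) if diffusion_rows else None
    return ReactionNetwork(
        species=species,
        parameters=parameters,
        reactions=reactions,
        kind=kind,
        diffusion=diffusion,
        name=name,
    )


def load_model(source) -> ReactionNetwork:
    """Load a model from a path or from schema text.

    Paths ending in ``.xml`` or ``.sbml`` go through the SBML importer.
    """
    text = None
    if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
        path = os.fspath(source)
        if path.endswith((".xml", ".sbml")):
            return import_sbml(path)
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    if text is None:
        raise SchemaError(f"cannot load model from {source!r}")
    return parse_model_text(text)


def serialize_model(net: ReactionNetwork) -> str:
    """Write a network back out in the native schema (round-trips exactly)."""
    lines = [f"model {net.name}", f"kind {net.kind}", "", "species"]
    for s in net.species:
        flag = " boundary" if s.is_boundary else ""
        lines.append(f"  {s.id} = {s.initial_amount!r}{flag}")
    lines += ["", "parameters"]
    for p in net.parameters:
        lines.append(f"  {p.id} = {p.value!r}")
    lines += ["", "reactions"]
    for r in net.reactions:
        lhs = " + ".join(
            (f"{-c} {sid}" if c < -1 else sid) for sid, c in r.stoichiometry.items() if c < 0
        )
        rhs = " + ".join(
            (f"{c} {sid}" if c > 1 else sid) for sid, c in r.stoichiometry.items() if c > 0
        )
        lines.append(f"  {r.id}: {lhs} -> {rhs} ; {r.rate_expression}")
    if net.kind == "langevin" and net.diffusion is not None:
        lines += ["", "diffusion"]
        for row in np.asarray(net.diffusion, float):
            lines.append("  " + " ".join(repr(float(x)) for x in row))
    return "\n".join(lines) + "\n"


def import_sbml(path: str) -> ReactionNetwork:
    """Import an SBML level-3 model, mapping kinetic laws into the native grammar.

    Unsupported constructs (events, rules, function definitions, dynamic
    compartments, non-arithmetic kinetic laws) are rejected with a clear error.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - availability depends on env
        raise SchemaError("SBML import requires python-libsbml") from exc

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise SchemaError(f"SBML parse errors in {path}")
    model = doc.getModel()
    if model is None:
        raise SchemaError(f"no model in {path}")
    for attr, label in [
        ("getNumEvents", "events"),
        ("getNumRules", "rules"),
        ("getNumFunctionDefinitions", "function definitions"),
        ("getNumConstraints", "constraints"),
    ]:
        if getattr(model, attr)() > 0:
            raise SchemaError(f"SBML import: {label} are not supported")

    species = []
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        amount = s.getInitialAmount() if s.isSetInitialAmount() else s.getInitialConcentration()
        species.append(Species(s.getId(), float(amount or 0.0), s.getBoundaryCondition()))
    parameters = []
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        parameters.append(Parameter(p.getId(), float(p.getValue())))

    reactions = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        stoich: dict[str, int] = {}
        boundary = {s.id for s in species if s.is_boundary}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0) - int(ref.getStoichiometry())
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0) + int(ref.getStoichiometry())
        stoich = {k: v for k, v in stoich.items() if v != 0}
        kl = r.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise SchemaError(f"SBML reaction {r.getId()!r} has no kinetic law")
        if kl.getNumParameters() > 0 or kl.getNumLocalParameters() > 0:
            raise SchemaError(f"SBML reaction {r.getId()!r}: local parameters not supported")
        formula = libsbml.formulaToL3String(kl.getMath())
        reactions.append(Reaction(r.getId(), stoich, formula))

    return ReactionNetwork(
        species=species,
        parameters=parameters,
        reactions=reactions,
        kind="markov-jump",
        name=model.getId() or "sbml_model",
    )
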