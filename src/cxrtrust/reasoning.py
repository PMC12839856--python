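"""Fuzzy ontology-aligned reasoning over saliency evidence.

The saliency layer summarises each (image, class) pair into a seven-component
evidence vector — the class probability plus six normalised spatial fractions
describing where the most-activated pixels lie relative to anatomy
(inside lungs+heart, over the heart, apical, basal, pleural rim, peri-cardiac
band).  This module converts those components into fuzzy predicates with
piecewise-linear memberships (ramp_up / ramp_down), combines them through a
per-class rule base using the product t-norm (AND) and probabilistic sum
(OR), and reports the maximum rule activation as an ontology support score
s_ont ∈ [0, 1].  Support can legitimately diverge from the raw probability:
a high-probability prediction whose saliency sits in an implausible location
earns low support.

A lightweight class hierarchy maps each dataset label to an ontology concept
(subclass of ThoracicAbnormality, or NormalFinding for "No finding") with
typical locations and imaging patterns, supports composite concepts such as
cardiomegaly_with_effusion, renders deterministic radiology-style
narratives, and exports/parses the hierarchy as RDF/OWL Turtle text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .anatomy import RegionSet
from .cam import CamHeatmap, TopPMask, anatomy_overlap, inside_energy_ratio
from .labels import CLASS_NAMES, NO_FINDING_INDEX, canonical_class_name

__all__ = [
    "EvidenceVector", "MembershipFn", "Predicate", "FuzzyRule",
    "SupportResult", "OntologyEntry", "Narrative",
    "evidence_from_cam", "membership", "fuzzy_combine", "evaluate_support",
    "default_rulebase", "rulebase_to_json", "rulebase_from_json",
    "ontology_lookup", "detect_composites", "render_narrative",
    "export_ontology", "parse_ontology", "ONTOLOGY",
]

EVIDENCE_COMPONENTS = ("prob", "inside", "inside_heart", "apical", "basal",
                       "near_pleura", "near_heart")


@dataclass
class EvidenceVector:
    """Seven components, all in [0, 1]."""

    prob: float
    inside: float
    inside_heart: float
    apical: float
    basal: float
    near_pleura: float
    near_heart: float

    def __post_init__(self):
        for name in EVIDENCE_COMPONENTS:
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"evidence component {name}={v} outside [0,1]")
            setattr(self, name, min(v, 1.0))

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in EVIDENCE_COMPONENTS}


@dataclass(frozen=True)
class MembershipFn:
    """Piecewise-linear membership: ramp_up rises 0→1 over [a, b]."""

    kind: str  # "ramp_up" | "ramp_down"
    a: float
    b: float

    def __post_init__(self):
        if self.kind not in ("ramp_up", "ramp_down"):
            raise ValueError(f"unknown membership kind {self.kind!r}")
        if not self.a < self.b:
            raise ValueError("membership requires a < b")

    def __call__(self, x: float) -> float:
        return membership(x, self)


def membership(x: float, fn: MembershipFn) -> float:
    up = float(np.clip((x - fn.a) / (fn.b - fn.a), 0.0, 1.0))
    return up if fn.kind == "ramp_up" else 1.0 - up


def fuzzy_combine(op: str, values: list[float]) -> float:
    """Product t-norm AND, probabilistic-sum OR (left fold), complement NOT."""
    vals = [float(v) for v in values]
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError("fuzzy values must lie in [0, 1]")
    if op == "AND":
        return float(np.prod(vals)) if vals else 1.0
    if op == "OR":
        acc = 0.0
        for v in vals:
            acc = acc + v - acc * v
        return acc
    if op == "NOT":
        if len(vals) != 1:
            raise ValueError("NOT takes exactly one operand")
        return 1.0 - vals[0]
    raise ValueError(f"unknown fuzzy operator {op!r}")


# -- rule expression tree ---------------------------------------------------

@dataclass(frozen=True)
class Predicate:
    component: str
    fn: MembershipFn

    def __post_init__(self):
        if self.component not in EVIDENCE_COMPONENTS:
            raise ValueError(f"unknown evidence component {self.component!r}")

    def evaluate(self, e: EvidenceVector) -> float:
        return membership(getattr(e, self.component), self.fn)

    def to_obj(self):
        return {"pred": self.component, "kind": self.fn.kind,
                "a": self.fn.a, "b": self.fn.b}


@dataclass(frozen=True)
class Node:
    op: str                      # AND | OR | NOT
    args: tuple                  # Predicate | Node

    def evaluate(self, e: EvidenceVector) -> float:
        return fuzzy_combine(self.op, [a.evaluate(e) for a in self.args])

    def to_obj(self):
        return {"op": self.op, "args": [a.to_obj() for a in self.args]}


def _expr_from_obj(obj) -> Predicate | Node:
    if "pred" in obj:
        return Predicate(obj["pred"], MembershipFn(obj["kind"],
                                                   obj["a"], obj["b"]))
    return Node(obj["op"], tuple(_expr_from_obj(a) for a in obj["args"]))


@dataclass(frozen=True)
class FuzzyRule:
    name: str
    target_class: str
    expr: Predicate | Node

    def activation(self, e: EvidenceVector) -> float:
        return self.expr.evaluate(e)


@dataclass
class SupportResult:
    class_name: str
    support: float
    winning_rule: str
    rule_activations: dict[str, float]


def evaluate_support(e: EvidenceVector,
                     rules: list[FuzzyRule]) -> SupportResult:
    """s_ont = maximum rule activation over the class's rules."""
    if not rules:
        raise ValueError("empty rule list")
    acts = {r.name: r.activation(e) for r in rules}
    winner = max(acts, key=acts.get)
    return SupportResult(rules[0].target_class, acts[winner], winner, acts)


# -- default rule base ------------------------------------------------------

_UP = MembershipFn("ramp_up", 0.2, 0.6)          # area-region predicates
# thin-band regions (pleural rim, peri-cardiac annulus) occupy only a small
# fraction of any area-proportional saliency mask, so their ramps are scaled
# down accordingly
_BAND_UP = MembershipFn("ramp_up", 0.05, 0.25)
_PROB_HIGH = MembershipFn("ramp_up", 0.5, 0.9)
_PROB_DOWN = MembershipFn("ramp_down", 0.5, 0.9)

_PARENCHYMAL = ("Consolidation", "Infiltration", "Lung opacity", "ILD",
                "Pulmonary fibrosis", "Nodule/Mass", "Atelectasis",
                "Calcification")
_GENERIC = ("Aortic enlargement", "Other lesion", "Pleural thickening")


def _and(*args):
    return Node("AND", tuple(args))


def _not(arg):
    return Node("NOT", (arg,))


def default_rulebase() -> dict[str, list[FuzzyRule]]:
    """Hand-crafted per-class rules encoding radiological priors.

    Effusion wants basal, pleural, intrapulmonary activation with high
    probability; cardiomegaly wants cardiac-silhouette overlap; pneumothorax
    wants apical, pleural, heart-sparing activation; parenchymal classes
    want intrapulmonary activation away from the mediastinum (fibrosis gets
    an extra basal-accented rule); remaining classes use a generic
    inside-thorax rule.  "No finding" is supported when no abnormality is
    probable (its evidence ``prob`` is the maximum abnormality probability).
    """
    rb: dict[str, list[FuzzyRule]] = {}
    p = Predicate
    rb["Pleural effusion"] = [FuzzyRule(
        "effusion_basal_pleural", "Pleural effusion",
        _and(p("basal", _UP), p("near_pleura", _BAND_UP), p("inside", _UP),
             p("prob", _PROB_HIGH)))]
    rb["Cardiomegaly"] = [FuzzyRule(
        "cardiomegaly_cardiac_overlap", "Cardiomegaly",
        _and(p("inside_heart", _UP), p("prob", _PROB_HIGH)))]
    rb["Pneumothorax"] = [FuzzyRule(
        "pneumothorax_apical_pleural_heart_sparing", "Pneumothorax",
        _and(p("apical", _UP), p("near_pleura", _BAND_UP),
             _not(p("near_heart", _BAND_UP)), p("prob", _PROB_HIGH)))]
    for name in _PARENCHYMAL:
        rb[name] = [FuzzyRule(
            "parenchymal_noncardiac", name,
            _and(p("inside", _UP), _not(p("inside_heart", _UP)),
                 p("prob", _PROB_HIGH)))]
    rb["Pulmonary fibrosis"].append(FuzzyRule(
        "fibrosis_basal_accent", "Pulmonary fibrosis",
        _and(p("inside", _UP), p("basal", _UP), p("prob", _PROB_HIGH))))
    for name in _GENERIC:
        rb[name] = [FuzzyRule(
            "generic_pulmonary", name,
            _and(p("inside", _UP), p("prob", _PROB_HIGH)))]
    rb["No finding"] = [FuzzyRule(
        "no_finding_low_abnormality_prob", "No finding",
        p("prob", _PROB_DOWN))]
    assert set(rb) == set(CLASS_NAMES)
    return rb


def rulebase_to_json(rb: dict[str, list[FuzzyRule]]) -> str:
    return json.dumps({
        cls: [{"name": r.name, "target_class": r.target_class,
               "expr": r.expr.to_obj()} for r in rules]
        for cls, rules in rb.items()
    }, indent=2)


def rulebase_from_json(text: str) -> dict[str, list[FuzzyRule]]:
    obj = json.loads(text)
    return {cls: [FuzzyRule(r["name"], r["target_class"],
                            _expr_from_obj(r["expr"])) for r in rules]
            for cls, rules in obj.items()}


# -- evidence extraction ----------------------------------------------------

def evidence_from_cam(heatmap: CamHeatmap | np.ndarray, top_p: TopPMask,
                      regions: RegionSet, prob: float,
                      mode: str = "fraction") -> EvidenceVector:
    """Summarise a class heatmap into the seven-component evidence vector.

    The spatial components are fractions of the selected (top-p) pixels
    lying in each region (``mode='fraction'``, default) or fractions of the
    heatmap's total energy (``mode='energy'``).  An empty top-p mask yields
    all-zero spatial evidence.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must lie in [0, 1]")
    region_map = {
        "inside": regions.lungs_heart,
        "inside_heart": regions.heart,
        "apical": regions.apical,
        "basal": regions.basal,
        "near_pleura": regions.pleural_band,
        "near_heart": regions.near_heart,
    }
    comp: dict[str, float] = {"prob": float(prob)}
    if mode == "fraction":
        for name, region in region_map.items():
            comp[name] = anatomy_overlap(top_p, region)
    elif mode == "energy":
        for name, region in region_map.items():
            comp[name] = inside_energy_ratio(heatmap, region)
    else:
        raise ValueError(f"unknown evidence mode {mode!r}")
    return EvidenceVector(**comp)


def evidence_for_no_finding(probs: np.ndarray) -> EvidenceVector:
    """Evidence for the normal-case rule: prob = max abnormality probability."""
    probs = np.asarray(probs, dtype=float)
    abnormal = np.delete(probs, NO_FINDING_INDEX)
    return EvidenceVector(float(abnormal.max()), 0, 0, 0, 0, 0, 0)


# -- ontology ---------------------------------------------------------------

@dataclass(frozen=True)
class OntologyEntry:
    dataset_label: str
    owl_class: str
    superclass: str              # ThoracicAbnormality | NormalFinding
    locations: tuple[str, ...]
    patterns: tuple[str, ...]


ONTOLOGY: dict[str, OntologyEntry] = {e.dataset_label: e for e in [
    OntologyEntry("Aortic enlargement", "AorticEnlargement",
                  "ThoracicAbnormality", ("Aorta",),
                  ("AorticContourEnlargementPattern",)),
    OntologyEntry("Atelectasis", "Atelectasis", "ThoracicAbnormality",
                  ("Lung",), ("VolumeLossPattern",)),
    OntologyEntry("Calcification", "Calcification", "ThoracicAbnormality",
                  ("Lung",), ("CalcifiedGranuloma", "CalcifiedLesion")),
    OntologyEntry("Cardiomegaly", "Cardiomegaly", "ThoracicAbnormality",
                  ("Heart",), ("EnlargedCardiacSilhouettePattern",)),
    OntologyEntry("Consolidation", "Consolidation", "ThoracicAbnormality",
                  ("Lung",), ("ConsolidationPattern",)),
    OntologyEntry("ILD", "ILD", "ThoracicAbnormality",
                  ("Lung",), ("InterstitialNodularPattern",)),
    OntologyEntry("Infiltration", "Infiltration", "ThoracicAbnormality",
                  ("Lung",), ("NonSpecificInfiltrativePattern",)),
    OntologyEntry("Lung opacity", "LungOpacity", "ThoracicAbnormality",
                  ("Lung",), ("OpacityPattern",)),
    OntologyEntry("Nodule/Mass", "NoduleOrMassFinding", "ThoracicAbnormality",
                  ("Lung",), ("NodulePattern", "MassPattern")),
    OntologyEntry("Other lesion", "OtherLesion", "ThoracicAbnormality",
                  (), ()),
    OntologyEntry("Pleural effusion", "PleuralEffusion",
                  "ThoracicAbnormality", ("PleuralSpace", "CostophrenicAngle"),
                  ("EffusionPattern",)),
    OntologyEntry("Pleural thickening", "PleuralThickening",
                  "ThoracicAbnormality", ("PleuralSpace",),
                  ("PleuralThickeningPattern",)),
    OntologyEntry("Pneumothorax", "Pneumothorax", "ThoracicAbnormality",
                  ("PleuralSpace",), ("PneumothoraxPattern",)),
    OntologyEntry("Pulmonary fibrosis", "PulmonaryFibrosis",
                  "ThoracicAbnormality", ("Lung", "BasalZone"),
                  ("FibroticPattern",)),
    OntologyEntry("No finding", "NoFinding", "NormalFinding",
                  (), ("NormalCXRStudy",)),
]}

COMPOSITE_DEFINITIONS = {
    "cardiomegaly_with_effusion": ("Cardiomegaly", "Pleural effusion"),
}


def ontology_lookup(label: str) -> OntologyEntry:
    return ONTOLOGY[canonical_class_name(label)]


def detect_composites(supports: dict[str, float], probs: dict[str, float],
                      prob_threshold: float = 0.5,
                      support_threshold: float = 0.5) -> list[str]:
    """Assert composite concepts whose members all pass both thresholds."""
    out = []
    for name, members in COMPOSITE_DEFINITIONS.items():
        if all(probs.get(m, 0.0) > prob_threshold
               and supports.get(m, 0.0) > support_threshold
               for m in members):
            out.append(name)
    return out


# -- narratives -------------------------------------------------------------

@dataclass
class Narrative:
    class_name: str
    text: str
    prob: float
    support: float
    evidence: dict[str, float]


def render_narrative(class_name: str, e: EvidenceVector, support: float,
                     prob: float,
                     ontology: OntologyEntry | None = None) -> Narrative:
    """Deterministic radiology-style sentence for one class prediction."""
    class_name = canonical_class_name(class_name)
    entry = ontology or ontology_lookup(class_name)
    zones = {"apical": e.apical, "basal": e.basal,
             "juxta-cardiac": e.inside_heart}
    zone = max(zones, key=zones.get)
    pattern = entry.patterns[0] if entry.patterns else "NonSpecificPattern"
    pleural = (" with pleural-band accentuation"
               if e.near_pleura >= 0.5 else "")
    text = (f"{class_name}: predominantly {zone} activation"
            f"{pleural}; {e.inside:.0%} of the salient region lies within "
            f"the lungs/heart. Imaging pattern: {pattern} "
            f"({entry.owl_class} ⊑ {entry.superclass}). "
            f"p = {prob:.2f}, ontology support ≈ {support:.2f}.")
    return Narrative(class_name, text, prob, support, e.as_dict())


# -- OWL export -------------------------------------------------------------

_CXR_NS = "http://cxrtrust.local/cxr-cdss#"


def export_ontology(entries: dict[str, OntologyEntry] | None = None,
                    composites: dict[str, tuple[str, ...]] | None = None
                    ) -> str:
    """Serialise the class hierarchy as RDF/OWL Turtle text.

    Emits one owl:Class per label with rdfs:subClassOf its superclass,
    annotation properties for typical locations and imaging patterns, a
    disjointness axiom between ThoracicAbnormality and NormalFinding, and
    composite concepts as intersections of their members.
    """
    from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
    from rdflib.namespace import OWL

    entries = ONTOLOGY if entries is None else entries
    composites = (COMPOSITE_DEFINITIONS if composites is None
                  else composites)
    cxr = Namespace(_CXR_NS)
    g = Graph()
    g.bind("cxr", cxr)
    g.bind("owl", OWL)
    for root in ("ThoracicAbnormality", "NormalFinding"):
        g.add((cxr[root], RDF.type, OWL.Class))
    g.add((cxr.ThoracicAbnormality, OWL.disjointWith, cxr.NormalFinding))
    for entry in entries.values():
        cls = cxr[entry.owl_class]
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, cxr[entry.superclass]))
        g.add((cls, RDFS.label, Literal(entry.dataset_label)))
        for loc in entry.locations:
            g.add((cls, cxr.hasTypicalLocation, Literal(loc)))
        for pat in entry.patterns:
            g.add((cls, cxr.hasImagingPattern, Literal(pat)))
    for name, members in composites.items():
        node = cxr[name]
        g.add((node, RDF.type, OWL.Class))
        g.add((node, RDFS.subClassOf, cxr.ThoracicAbnormality))
        for m in members:
            g.add((node, cxr.hasMember, cxr[entries[m].owl_class]))
    return g.serialize(format="turtle")


def parse_ontology(turtle_text: str) -> dict[str, OntologyEntry]:
    """Parse Turtle produced by :func:`export_ontology` back to entries."""
    from rdflib import Graph, Namespace, RDFS
    cxr = Namespace(_CXR_NS)
    g = Graph()
    g.parse(data=turtle_text, format="turtle")
    out: dict[str, OntologyEntry] = {}
    for cls, label in g.subject_objects(RDFS.label):
        owl_class = str(cls).split("#")[-1]
        superclass = [str(o).split("#")[-1]
                      for o in g.objects(cls, RDFS.subClassOf)][0]
        locations = tuple(sorted(str(o) for o in
                                 g.objects(cls, cxr.hasTypicalLocation)))
        patterns = tuple(sorted(str(o) for o in
                                g.objects(cls, cxr.hasImagingPattern)))
        out[str(label)] = OntologyEntry(str(label), owl_class, superclass,
                                        locations, patterns)
    return out
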