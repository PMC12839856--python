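"""Fuzzy memberships, rule evaluation, ontology mapping, narratives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cxrtrust.cam import top_p_mask
from cxrtrust.labels import CLASS_NAMES
from cxrtrust.reasoning import (EVIDENCE_COMPONENTS, EvidenceVector,
                                FuzzyRule, MembershipFn, Node, Predicate,
                                default_rulebase, detect_composites,
                                evaluate_support, evidence_from_cam,
                                evidence_for_no_finding, export_ontology,
                                fuzzy_combine, membership, ontology_lookup,
                                parse_ontology, render_narrative,
                                rulebase_from_json, rulebase_to_json, ONTOLOGY)
from cxrtrust.synth import synth_anatomy

unit = st.floats(0.0, 1.0)


class TestMembership:
    def test_ramp_values(self):
        up = MembershipFn("ramp_up", 0.2, 0.6)
        assert membership(0.4, up) == pytest.approx(0.5)
        assert membership(0.2, up) == 0.0
        assert membership(0.9, up) == 1.0
        down = MembershipFn("ramp_down", 0.2, 0.6)
        assert membership(0.7, down) == 0.0
        assert membership(0.1, down) == 1.0

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="a < b"):
            MembershipFn("ramp_up", 0.6, 0.2)


class TestFuzzyCombine:
    def test_worked_examples(self):
        assert fuzzy_combine("AND", [0.8, 0.5]) == pytest.approx(0.4)
        assert fuzzy_combine("OR", [0.8, 0.5]) == pytest.approx(0.9)
        assert fuzzy_combine("NOT", [0.3]) == pytest.approx(0.7)

    @settings(max_examples=50, derandomize=True)
    @given(unit, unit, unit)
    def test_tnorm_tconorm_axioms(self, a, b, c):
        """Commutativity, associativity and identity elements of the
        product t-norm and probabilistic sum."""
        assert fuzzy_combine("AND", [a, b]) == pytest.approx(
            fuzzy_combine("AND", [b, a]))
        assert fuzzy_combine("OR", [a, b]) == pytest.approx(
            fuzzy_combine("OR", [b, a]))
        assert fuzzy_combine("AND", [fuzzy_combine("AND", [a, b]), c]) == \
            pytest.approx(fuzzy_combine("AND", [a, b, c]))
        assert fuzzy_combine("OR", [fuzzy_combine("OR", [a, b]), c]) == \
            pytest.approx(fuzzy_combine("OR", [a, b, c]))
        assert fuzzy_combine("AND", [a, 1.0]) == pytest.approx(a)
        assert fuzzy_combine("OR", [a, 0.0]) == pytest.approx(a)
        assert 0.0 <= fuzzy_combine("OR", [a, b]) <= 1.0


class TestSupport:
    @staticmethod
    def raw_rule(name, components):
        """AND of identity ramps, so memberships equal the raw evidence."""
        ident = MembershipFn("ramp_up", 0.0, 1.0)
        return FuzzyRule(name, "Pleural effusion", Node(
            "AND", tuple(Predicate(c, ident) for c in components)))

    def test_max_over_rules_and_winner(self):
        e = EvidenceVector(0.2, 0.7, 0, 0, 0, 0, 0)
        weak = self.raw_rule("weak", ("prob",))          # 0.2
        strong = self.raw_rule("strong", ("inside",))    # 0.7
        res = evaluate_support(e, [weak, strong])
        assert res.support == pytest.approx(0.7)
        assert res.winning_rule == "strong"
        assert res.rule_activations == pytest.approx(
            {"weak": 0.2, "strong": 0.7})

    def test_effusion_style_product(self):
        """AND over memberships (0.9, 1.0, 1.0, 0.8) multiplies to 0.72."""
        e = EvidenceVector(prob=0.9, inside=0.8, inside_heart=0,
                           apical=0, basal=1.0, near_pleura=1.0,
                           near_heart=0)
        rule = self.raw_rule("effusion_like",
                             ("prob", "basal", "near_pleura", "inside"))
        assert evaluate_support(e, [rule]).support == pytest.approx(0.72)

    def test_all_zero_memberships(self):
        e = EvidenceVector(0, 0, 0, 0, 0, 0, 0)
        rule = self.raw_rule("r", ("prob", "inside"))
        assert evaluate_support(e, [rule]).support == 0.0

    def test_empty_rule_list_rejected(self):
        with pytest.raises(ValueError, match="empty rule"):
            evaluate_support(EvidenceVector(0, 0, 0, 0, 0, 0, 0), [])


class TestDefaultRulebase:
    def test_every_class_covered(self):
        rb = default_rulebase()
        assert set(rb) == set(CLASS_NAMES)
        assert all(len(rules) >= 1 for rules in rb.values())

    def test_json_roundtrip(self):
        rb = default_rulebase()
        rb2 = rulebase_from_json(rulebase_to_json(rb))
        e = EvidenceVector(0.93, 0.8, 0.1, 0.1, 0.7, 0.3, 0.05)
        for cls in CLASS_NAMES:
            assert evaluate_support(e, rb[cls]).support == pytest.approx(
                evaluate_support(e, rb2[cls]).support)

    def test_basal_pleural_evidence_prefers_effusion(self):
        rb = default_rulebase()
        e = EvidenceVector(prob=0.95, inside=0.9, inside_heart=0.02,
                           apical=0.02, basal=0.85, near_pleura=0.3,
                           near_heart=0.02)
        s_eff = evaluate_support(e, rb["Pleural effusion"]).support
        s_pnx = evaluate_support(e, rb["Pneumothorax"]).support
        assert s_eff > s_pnx

    def test_support_monotone_in_positive_components(self):
        """Finite-difference probes: nudging any positively-referenced
        component up never decreases the class support."""
        rb = default_rulebase()
        base = {"prob": 0.7, "inside": 0.5, "inside_heart": 0.3,
                "apical": 0.4, "basal": 0.4, "near_pleura": 0.15,
                "near_heart": 0.1}
        positives = {
            "Pleural effusion": ("prob", "inside", "basal", "near_pleura"),
            "Cardiomegaly": ("prob", "inside_heart"),
            "Pneumothorax": ("prob", "apical", "near_pleura"),
            "Consolidation": ("prob", "inside"),
        }
        for cls, comps in positives.items():
            s0 = evaluate_support(EvidenceVector(**base), rb[cls]).support
            for comp in comps:
                bumped = dict(base)
                bumped[comp] = min(1.0, base[comp] + 0.1)
                s1 = evaluate_support(EvidenceVector(**bumped),
                                      rb[cls]).support
                assert s1 >= s0 - 1e-12

    def test_high_prob_implausible_location_has_low_support(self):
        """The interpretive point: probability and support can diverge."""
        rb = default_rulebase()
        e = EvidenceVector(prob=0.95, inside=0.05, inside_heart=0.0,
                           apical=0.0, basal=0.05, near_pleura=0.0,
                           near_heart=0.0)
        for cls in ("Pleural effusion", "Cardiomegaly", "Consolidation"):
            assert evaluate_support(e, rb[cls]).support < 0.2
        assert e.prob > 0.9

    def test_supports_bounded(self):
        rb = default_rulebase()
        rng = np.random.default_rng(0)
        for _ in range(20):
            e = EvidenceVector(*rng.random(7))
            for cls in CLASS_NAMES:
                assert 0.0 <= evaluate_support(e, rb[cls]).support <= 1.0


class TestEvidence:
    def test_pixel_counting_oracle(self):
        regions, _ = synth_anatomy(0, size=64)
        hm = np.zeros((64, 64))
        hm[regions.lungs] = 1.0        # saliency exactly the lungs
        mask = top_p_mask(hm + 1e-9 * np.random.default_rng(0).random(
            (64, 64)), p=regions.lungs.mean())
        e = evidence_from_cam(hm, mask, regions, prob=0.9)
        expected_inside = (mask.pixels & regions.lungs_heart).sum() / \
            mask.pixels.sum()
        assert e.inside == pytest.approx(expected_inside)
        expected_basal = (mask.pixels & regions.basal).sum() / \
            mask.pixels.sum()
        assert e.basal == pytest.approx(expected_basal)
        assert e.apical + e.basal <= e.inside + 1e-9 + \
            (mask.pixels & regions.heart).sum() / mask.pixels.sum()

    def test_no_finding_evidence_uses_max_abnormality_prob(self):
        probs = np.zeros(15)
        probs[3] = 0.8
        probs[14] = 0.99
        e = evidence_for_no_finding(probs)
        assert e.prob == pytest.approx(0.8)

    def test_component_range_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            EvidenceVector(1.2, 0, 0, 0, 0, 0, 0)


class TestOntology:
    def test_lookup_superclasses(self):
        assert ontology_lookup("Pleural effusion").superclass == \
            "ThoracicAbnormality"
        assert ontology_lookup("No finding").superclass == "NormalFinding"
        with pytest.raises(ValueError):
            ontology_lookup("Not a label")

    def test_every_label_has_one_entry(self):
        assert set(ONTOLOGY) == set(CLASS_NAMES)

    def test_composites_threshold_rule(self):
        sup = {"Cardiomegaly": 0.8, "Pleural effusion": 0.9}
        prob = {"Cardiomegaly": 0.9, "Pleural effusion": 0.9}
        assert detect_composites(sup, prob) == ["cardiomegaly_with_effusion"]
        weak = dict(sup, **{"Pleural effusion": 0.2})
        assert detect_composites(weak, prob) == []

    def test_turtle_export_roundtrip_and_disjointness(self):
        text = export_ontology()
        assert text.count("owl:Class") >= 15
        assert "owl:disjointWith" in text
        parsed = parse_ontology(text)
        assert set(parsed) == set(ONTOLOGY)
        for label, entry in ONTOLOGY.items():
            got = parsed[label]
            assert got.owl_class == entry.owl_class
            assert got.superclass == entry.superclass
            assert set(got.locations) == set(entry.locations)
            assert set(got.patterns) == set(entry.patterns)


class TestNarrative:
    def test_contains_zone_pattern_and_two_decimal_scores(self):
        e = EvidenceVector(prob=0.99, inside=0.9, inside_heart=0.05,
                           apical=0.1, basal=0.8, near_pleura=0.6,
                           near_heart=0.02)
        n = render_narrative("Pleural effusion", e, support=0.87, prob=0.99)
        assert "basal" in n.text
        assert "EffusionPattern" in n.text
        assert "p = 0.99" in n.text
        assert "0.87" in n.text

    def test_deterministic(self):
        e = EvidenceVector(0.5, 0.5, 0.5, 0.5, 0.4, 0.3, 0.2)
        a = render_narrative("Cardiomegaly", e, 0.4, 0.5)
        b = render_narrative("Cardiomegaly", e, 0.4, 0.5)
        assert a.text == b.text
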