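"""Percentile colour-coding, symbolic/registry agreement, SBML export."""

import numpy as np
import pandas as pd
import pytest

from hepfast import model_core as mc
from hepfast import report


class TestColorcode:
    def test_identical_values_single_class(self):
        m = pd.DataFrame(np.full((10, 4), 0.3))
        coded = report.percentile_colorcode(m)
        assert (coded.classes.to_numpy() == "green").all()

    def test_single_hot_cell_is_red(self):
        values = np.full((78, 1), 1e-5)
        values[10, 0] = 0.9
        coded = report.percentile_colorcode(pd.DataFrame(values))
        flat = coded.classes.to_numpy().ravel()
        n_red = sum(c in report.RED_CLASSES for c in flat)
        assert n_red == 1
        assert coded.classes.iloc[10, 0] in report.RED_CLASSES

    def test_above_median_column_flagged(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 0.2, (20, 5))
        values[:, 2] = rng.uniform(0.5, 0.9, 20)   # whole column hot
        coded = report.percentile_colorcode(
            pd.DataFrame(values, columns=list("abcde")))
        assert "c" in coded.above_median_columns
        assert "a" not in coded.above_median_columns

    def test_validation(self):
        with pytest.raises(ValueError):
            report.percentile_colorcode(pd.DataFrame(np.empty((0, 0))))
        with pytest.raises(ValueError):
            report.percentile_colorcode(pd.DataFrame([[0.5, 1.5]]))
        with pytest.raises(ValueError):
            report.percentile_colorcode(pd.DataFrame([[0.5, np.nan]]))

    def test_render_heatmap_writes_file(self, tmp_path):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.uniform(0, 1, (12, 6)))
        out = tmp_path / "heat.png"
        report.render_heatmap(m, out, title="test")
        assert out.stat().st_size > 0


class TestSymbolicAgreement:
    def test_symbolic_rates_match_registry(self, params, rng):
        """The sympy rate table and the registry lambdas agree pointwise."""
        import sympy as sp

        from hepfast import _symbolic
        rates_sym = _symbolic.symbolic_rates()
        s = _symbolic.state_symbols()
        p_sym = _symbolic.param_symbols()
        subs_p = {p_sym[name]: value for name, value in params.items()}
        for _ in range(3):
            y = rng.uniform(0.01, 30.0, len(mc.STATE_NAMES))
            subs = dict(subs_p)
            subs.update({s[n]: v for n, v in zip(mc.STATE_NAMES, y)})
            num = mc.reaction_rates(y, params)
            for rxn in mc.REACTIONS:
                if rxn.rid in ("v3", "v43"):    # diet inputs, bolus = 0
                    continue
                sym_val = float(rates_sym[rxn.rid].subs(subs))
                assert sym_val == pytest.approx(num[rxn.rid], rel=1e-9), \
                    rxn.rid

    def test_jacobian_matches_finite_differences(self, params, lunch1_init):
        # moderate k_d via the override mechanism: with the documented
        # 1.733e14 the insulin row is O(1e16) and finite differences are
        # pure cancellation noise, which is the very reason the analytic
        # Jacobian exists
        p = params.replace(k_d=1e-2)
        from hepfast._symbolic import jacobian_function
        jac = jacobian_function()
        pv = np.array(p.struct(), dtype=float)
        J = jac(np.asarray(lunch1_init, dtype=float), pv)
        assert J.shape == (23, 23)
        for j in (0, 1, 7, 22):   # spot-check a few columns
            h = max(abs(lunch1_init[j]), 1.0) * 1e-4
            yp = np.array(lunch1_init, dtype=float)
            ym = yp.copy()
            yp[j] += h
            ym[j] -= h
            fd = (mc.evaluate_rhs(yp, p)
                  - mc.evaluate_rhs(ym, p)) / (2 * h)
            scale = np.maximum(np.abs(J[:, j]), 1.0)
            assert np.max(np.abs(fd - J[:, j]) / scale) < 1e-3


class TestSbmlExport:
    def test_document_structure(self):
        from lxml import etree

        from hepfast.sbml_export import model_to_sbml
        doc = etree.fromstring(model_to_sbml())
        ns = {"s": "http://www.sbml.org/sbml/level3/version2/core"}
        assert doc.attrib["level"] == "3" and doc.attrib["version"] == "2"
        species = doc.findall(".//s:species", ns)
        assert len(species) == 23
        assert len(doc.findall(".//s:reaction", ns)) == 45
        assert len(doc.findall(".//s:parameter", ns)) == 81
        compartments = {c.get("id")
                        for c in doc.findall(".//s:compartment", ns)}
        assert compartments == {"liver", "muscle", "adipose", "plasma"}
        # kinetic laws carry MathML
        laws = doc.findall(".//s:kineticLaw", ns)
        assert len(laws) == 45
        mathml = "{http://www.w3.org/1998/Math/MathML}math"
        assert all(law.find(mathml) is not None for law in laws)
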