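"""Control-normalized effect sizes (pZ), gene effects and T scores.

The brute-force oracle below recomputes every statistic with the plain
Python ``statistics`` module, independent of the pandas/numpy pipeline.
"""

import math
import statistics

import numpy as np
import pandas as pd
import pytest

from dropout3d import (
    Category,
    ControlSummary,
    GuideLibrary,
    GuideRecord,
    gene_table,
    gene_u,
    guide_pZ,
    screen_phenotypes,
    t_score,
)
from dropout3d.phenotype import PhenotypeError, control_summary
from dropout3d.screen import CONTROL_GENE


# -- independent oracle --------------------------------------------------

def oracle_u(pzs):
    return statistics.median(pzs)


def oracle_t(gene_pzs, ctrl_pzs, n_ctrl):
    """Pooled-variance phenotype score, straight from the printed form."""
    u_gene = statistics.median(gene_pzs)
    u_ctrl = statistics.median(ctrl_pzs)
    var_gene = statistics.variance(gene_pzs)
    var_ctrl = statistics.variance(ctrl_pzs)
    n_exp = len(gene_pzs)
    s_var = var_gene * (n_exp - 1) + var_ctrl * (n_ctrl - 1)
    return (u_gene - u_ctrl) / math.sqrt(s_var / n_exp + s_var / n_ctrl)


def spacers(n, seed=0):
    rng = np.random.default_rng(seed)
    out = set()
    while len(out) < n:
        out.add("".join("ACGT"[b] for b in rng.integers(0, 4, 18)))
    return sorted(out)


def library_of(gene_sizes, n_controls):
    sp = iter(spacers(sum(gene_sizes.values()) + n_controls, seed=42))
    records = []
    for gene, k in gene_sizes.items():
        for j in range(k):
            records.append(GuideRecord(f"{gene}_g{j}", gene, next(sp), Category.TARGETING))
    for j in range(n_controls):
        cat = Category.SAFE if j % 2 == 0 else Category.NON_TARGETING
        records.append(GuideRecord(f"ctl_{j}", CONTROL_GENE, next(sp), cat))
    return GuideLibrary(records)


def enrichment_frame(values):
    return pd.DataFrame({"log2fe": pd.Series(values)})


class TestGuidePZ:
    def test_zero_control_median_passthrough(self):
        lib = library_of({"G1": 1}, 3)
        enr = enrichment_frame(
            {"G1_g0": -1.3, "ctl_0": -0.2, "ctl_1": 0.0, "ctl_2": 0.2}
        )
        pz = guide_pZ(enr, lib)
        assert pz["G1_g0"] == pytest.approx(-1.3)

    def test_nonzero_control_median_subtracted(self):
        lib = library_of({"G1": 1}, 3)
        enr = enrichment_frame(
            {"G1_g0": -1.0, "ctl_0": 0.4, "ctl_1": 0.5, "ctl_2": 0.6}
        )
        assert guide_pZ(enr, lib)["G1_g0"] == pytest.approx(-1.5)

    def test_control_at_median_maps_to_zero(self):
        lib = library_of({"G1": 1}, 3)
        enr = enrichment_frame(
            {"G1_g0": 1.0, "ctl_0": 0.1, "ctl_1": 0.5, "ctl_2": 0.9}
        )
        assert guide_pZ(enr, lib)["ctl_1"] == pytest.approx(0.0)

    def test_no_controls_is_error(self):
        lib = library_of({"G1": 2}, 2)
        enr = enrichment_frame({"G1_g0": 0.5, "G1_g1": 0.25})
        with pytest.raises(PhenotypeError, match="control"):
            guide_pZ(enr, lib)

    def test_control_median_zero_invariant(self):
        rng = np.random.default_rng(9)
        lib = library_of({"G1": 4}, 20)
        vals = {f"G1_g{j}": rng.normal() for j in range(4)}
        vals |= {f"ctl_{j}": rng.normal() for j in range(20)}
        pz = guide_pZ(enrichment_frame(vals), lib)
        ctl = pz[[f"ctl_{j}" for j in range(20)]]
        assert float(ctl.median()) == pytest.approx(0.0, abs=1e-15)


class TestGeneU:
    def test_odd_median(self):
        lib = library_of({"G1": 3}, 2)
        pz = pd.Series({"G1_g0": -2.0, "G1_g1": -1.0, "G1_g2": 0.0})
        assert gene_u(pz, lib)["G1"] == pytest.approx(-1.0)

    def test_even_median_is_midpoint(self):
        lib = library_of({"G1": 2}, 2)
        pz = pd.Series({"G1_g0": -2.0, "G1_g1": -1.0})
        assert gene_u(pz, lib)["G1"] == pytest.approx(-1.5)

    def test_order_free(self):
        lib = library_of({"G1": 5}, 2)
        rng = np.random.default_rng(1)
        vals = {f"G1_g{j}": float(v) for j, v in enumerate(rng.normal(size=5))}
        fwd = gene_u(pd.Series(vals), lib)["G1"]
        rev = gene_u(pd.Series(dict(reversed(list(vals.items())))), lib)["G1"]
        assert fwd == rev


class TestTScore:
    WORKED_CTRL = ControlSummary("x", u_ctrl=0.0, var_ctrl=0.005, n_ctrl=10, n_control_guides=6)

    def test_worked_fixture(self):
        """4-guide gene vs 6 controls, n_ctrl=10: frozen hand arithmetic.

        gene pZ {-1.2, -1.0, -0.8, -1.0}: u = -1.0, var = 0.08/3
        controls {-0.1, -0.05, 0, 0, 0.05, 0.1}: u_ctrl = 0, var = 0.005
        S_var = (0.08/3)*3 + 0.005*9 = 0.125
        T = -1 / sqrt(0.125/4 + 0.125/10) = -4.7809...
        """
        gene_pzs = [-1.2, -1.0, -0.8, -1.0]
        var_gene = statistics.variance(gene_pzs)
        assert var_gene == pytest.approx(0.08 / 3)
        t = t_score(-1.0, var_gene, 4, self.WORKED_CTRL)
        assert t == pytest.approx(-1 / math.sqrt(0.04375), rel=1e-12)
        assert t == pytest.approx(-4.781, abs=5e-4)
        assert t == pytest.approx(
            oracle_t(gene_pzs, [-0.1, -0.05, 0, 0, 0.05, 0.1], 10), rel=1e-12
        )

    def test_zero_numerator_gives_zero(self):
        assert t_score(0.0, 0.3, 5, self.WORKED_CTRL) == 0.0

    def test_inflating_gene_variance_shrinks_magnitude(self):
        t1 = t_score(-1.0, 0.02, 4, self.WORKED_CTRL)
        t2 = t_score(-1.0, 0.08, 4, self.WORKED_CTRL)
        assert t1 < 0 and t2 < 0 and abs(t2) < abs(t1)

    def test_single_guide_undefined(self):
        assert math.isnan(t_score(-1.0, float("nan"), 1, self.WORKED_CTRL))

    def test_degenerate_constant_inputs_flagged_nan(self):
        ctrl = ControlSummary("x", 0.0, 0.0, 10, 6)
        assert math.isnan(t_score(-1.0, 0.0, 4, ctrl))

    def test_welch_variant_differs_but_keeps_sign(self):
        t_print = t_score(-1.0, 0.0266, 4, self.WORKED_CTRL, welch=False)
        t_welch = t_score(-1.0, 0.0266, 4, self.WORKED_CTRL, welch=True)
        assert t_print < 0 and t_welch < 0
        assert t_welch != pytest.approx(t_print)

    @pytest.mark.parametrize("trial", range(25))
    def test_oracle_equivalence_random_tables(self, trial):
        """Pipeline u_gene/T match brute-force statistics to 1e-9 rel."""
        rng = np.random.default_rng(100 + trial)
        n_genes = int(rng.integers(1, 5))
        sizes = {f"G{i}": int(rng.integers(2, 8)) for i in range(n_genes)}
        n_ctrl_guides = int(rng.integers(4, 12))
        lib = library_of(sizes, n_ctrl_guides)
        vals = {g: float(rng.normal(scale=1.5)) for g in lib.guide_ids}
        enr = enrichment_frame(vals)
        pz = guide_pZ(enr, lib)
        ctrl = control_summary(pz, lib, "cmp")
        table = gene_table(pz, lib, ctrl)
        ctrl_pzs = [pz[g] for g in lib.control_ids]
        for gene, size in sizes.items():
            gene_pzs = [pz[f"{gene}_g{j}"] for j in range(size)]
            assert table.loc[gene, "u_gene"] == pytest.approx(
                oracle_u(gene_pzs), rel=1e-9
            )
            assert table.loc[gene, "t_score"] == pytest.approx(
                oracle_t(gene_pzs, ctrl_pzs, ctrl.n_ctrl), rel=1e-9
            )

    def test_sign_matches_u_vs_uctrl(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            u = float(rng.normal())
            t = t_score(u, 0.05, 5, self.WORKED_CTRL)
            assert (t < 0) == (u < self.WORKED_CTRL.u_ctrl) or u == 0


class TestScreenPhenotypes:
    def test_location_equivariance(self, small_sim):
        """Adding a constant to all log2fe leaves pZ, u and T unchanged."""
        _, library, _, counts, design = small_sim
        phen = screen_phenotypes(counts, library, design, min_eligible=10)
        label = "3D_D7_vs_D0"
        base = phen[label]
        shifted_enr = base.guide_frame[["log2fe"]] + 3.7
        pz = guide_pZ(shifted_enr, library)
        assert np.allclose(pz, base.guide_frame["pZ"], atol=1e-12)
        ctrl = control_summary(pz, library, label)
        table = gene_table(pz, library, ctrl)
        assert np.allclose(table["u_gene"], base.genes["u_gene"], atol=1e-12)
        assert np.allclose(
            table["t_score"], base.genes["t_score"], atol=1e-9, equal_nan=True
        )

    def test_n_ctrl_is_targeting_guides_per_gene(self, small_sim):
        _, library, _, counts, design = small_sim
        phen = screen_phenotypes(counts, library, design, min_eligible=10)
        for p in phen.values():
            assert p.control.n_ctrl == pytest.approx(
                len(library.targeting_ids) / len(library.genes)
            )

    def test_neutral_genes_centred_at_zero(self, small_sim):
        """Known-neutral genes have u_gene distribution centred near 0."""
        _, library, truth, counts, design = small_sim
        phen = screen_phenotypes(counts, library, design, min_eligible=10)
        neutral = truth.genes_of("neutral")
        for p in phen.values():
            u = p.genes.loc[neutral, "u_gene"]
            se_genes = u.std(ddof=1) / np.sqrt(len(u))
            # the control-median estimate is a shared offset across all
            # genes of a comparison; its sampling error does not shrink
            # with the number of genes and belongs in the SE
            ctrl_pz = p.guide_frame.loc[library.control_ids, "pZ"]
            se_ctrl = 1.2533 * ctrl_pz.std(ddof=1) / np.sqrt(len(ctrl_pz))
            se = np.sqrt(se_genes**2 + se_ctrl**2)
            assert abs(u.mean()) < 3 * se

    def test_essential_genes_negative_t_in_both_conditions(self, small_sim):
        """Common-essential spike-ins score strongly negative T everywhere."""
        _, library, truth, counts, design = small_sim
        phen = screen_phenotypes(counts, library, design, min_eligible=10)
        ess = truth.genes_of("common_essential")
        neut = truth.genes_of("neutral")
        for p in phen.values():
            assert p.genes.loc[ess, "t_score"].max() < p.genes.loc[neut, "t_score"].min()

    def test_single_guide_gene_has_u_but_no_t(self):
        lib = library_of({"LONE": 1, "G2": 3}, 4)
        rng = np.random.default_rng(0)
        vals = {g: float(rng.normal()) for g in lib.guide_ids}
        pz = guide_pZ(enrichment_frame(vals), lib)
        ctrl = control_summary(pz, lib, "cmp")
        table = gene_table(pz, lib, ctrl)
        assert not math.isnan(table.loc["LONE", "u_gene"])
        assert math.isnan(table.loc["LONE", "t_score"])
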