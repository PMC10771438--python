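"""The per-protocol screen and the sign-concordant intersection."""

import numpy as np
import pandas as pd
import pytest

from propscreen.propensity import PropensityResult, propensity_from_panel
from propscreen.rankcorr import exact_null, exact_pvalue
from propscreen.screen import ScreenResult, intersect_candidates, screen_protocol
from propscreen.synthetic import ExpressionMatrix, PanelConfig, simulate_panel


def _propensity_from_ranks(ranks: dict[str, int], protocol: str) -> PropensityResult:
    """A propensity result whose ordering is given directly (rank 1 =
    highest propensity); scores are constructed to match."""
    lines = sorted(ranks)
    scores = pd.Series({ln: float(len(ranks) - ranks[ln]) for ln in lines})
    return PropensityResult(
        lines=tuple(lines),
        pc1_score=scores,
        pc1_rank=pd.Series({ln: ranks[ln] for ln in lines}),
        loadings=pd.Series({"PAX6": 1.0}),
        explained_variance=100.0,
        protocol=protocol,
    )


def _expression_from_line_means(means: pd.DataFrame, reps: int = 2,
                                noise: float = 0.0, seed: int = 0):
    rng = np.random.default_rng(seed)
    lines = list(means.columns)
    samples = [f"{ln}_r{k+1}" for ln in lines for k in range(reps)]
    values = np.repeat(means.to_numpy(), reps, axis=1)
    if noise:
        values = values + rng.normal(0, noise, size=values.shape)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=means.index, columns=samples),
        sample_annotations=pd.DataFrame(
            {
                "line": [ln for ln in lines for _ in range(reps)],
                "replicate": [k + 1 for _ in lines for k in range(reps)],
                "condition": "undifferentiated",
                "day": 0,
            },
            index=samples,
        ),
    )


class TestScreenProtocol:
    def test_perfect_planted_panel_fully_recovered(self):
        """At planted_rho = 1 and zero noise every planted gene is called
        significant with its planted sign."""
        cfg = PanelConfig(seed=1, noise_sd=0.0, planted_rho=1.0, n_probes=60)
        expr, susp, _, truth = simulate_panel(cfg)
        prop = propensity_from_panel(susp)
        res = screen_protocol(expr, prop, alpha=0.01)
        for row in truth.planted.itertuples(index=False):
            if row.direction == "+":
                assert row.gene_id in res.positive_set
            else:
                assert row.gene_id in res.negative_set

    def test_n_tested_bookkeeping(self, small_panel):
        cfg, (expr, susp, _, _) = small_panel
        prop = propensity_from_panel(susp)
        res = screen_protocol(expr, prop)
        assert res.n_tested == len(expr.probe_ids) == len(res.table)

    def test_line_mismatch_names_offenders(self, small_panel):
        cfg, (expr, susp, _, _) = small_panel
        prop = propensity_from_panel(susp)
        bad = ExpressionMatrix(
            values=expr.values.rename(columns={"line01_r1": "lineXX_r1"}),
            sample_annotations=expr.sample_annotations.rename(
                index={"line01_r1": "lineXX_r1"}
            ).assign(
                line=lambda d: d["line"].where(d.index != "lineXX_r1", "lineXX")
            ),
        )
        with pytest.raises(ValueError, match="lineXX"):
            screen_protocol(bad, prop)

    def test_rank_and_score_correlations_agree(self, small_panel):
        """Correlating against the PC1 rank vector equals correlating
        against the PC1 scores themselves (untied data)."""
        from propscreen.rankcorr import spearman_rs

        cfg, (expr, susp, _, _) = small_panel
        prop = propensity_from_panel(susp)
        res = screen_protocol(expr, prop)
        means = expr.line_means(condition="undifferentiated")
        for gene in means.index[:25]:
            direct = spearman_rs(
                means.loc[gene, list(prop.lines)],
                prop.pc1_score[list(prop.lines)],
            ).r_s
            got = float(res.table.set_index("gene_id").loc[gene, "r_s"])
            assert got == pytest.approx(direct, abs=1e-12)

    def test_permuted_labels_control_false_positives(self):
        """With line labels permuted (global null) the significant
        fraction stays near the achieved alpha of the exact null."""
        null10 = exact_null(10)
        achieved = exact_pvalue(0.794, null10)
        rng = np.random.default_rng(0)
        n_sig = n_tot = 0
        for seed in range(20):
            cfg = PanelConfig(seed=seed, n_probes=400, planted_pos=0,
                              planted_neg=0)
            expr, susp, _, _ = simulate_panel(cfg)
            prop = propensity_from_panel(susp)
            # permute the expression-to-line assignment
            perm = rng.permutation(list(prop.lines))
            mapping = dict(zip(prop.lines, perm))
            shuffled = ExpressionMatrix(
                values=expr.values,
                sample_annotations=expr.sample_annotations.assign(
                    line=expr.sample_annotations["line"].map(mapping)
                ),
            )
            res = screen_protocol(shuffled, prop, alpha=0.01, null=null10)
            n_sig += res.table["significant"].sum()
            n_tot += res.n_tested
        frac = n_sig / n_tot
        se = np.sqrt(achieved * (1 - achieved) / n_tot)
        assert frac <= achieved + 3 * se


class TestIntersectCandidates:
    def _screen(self, protocol, pos=(), neg=(), universe=("g1", "g2", "g3")):
        table = pd.DataFrame(
            {
                "gene_id": universe,
                "r_s": [0.9 if g in pos else -0.9 if g in neg else 0.1
                        for g in universe],
                "p_two_sided": [0.005 if g in pos or g in neg else 0.8
                                for g in universe],
                "direction": ["+" if g in pos else "-" if g in neg else "+"
                              for g in universe],
                "significant": [g in pos or g in neg for g in universe],
                "tied": False,
            }
        )
        return ScreenResult(
            protocol=protocol, table=table, positive_set=set(pos),
            negative_set=set(neg), n_tested=len(universe), alpha=0.01,
        )

    def test_shared_negative_isolated(self):
        """A gene negative in both protocols survives; genes significant
        in only one protocol do not — the single-common-candidate logic."""
        a = self._screen("suspension", pos=("g1",), neg=("g2",))
        b = self._screen("adhesion", pos=("g3",), neg=("g2",))
        inter = intersect_candidates([a, b])
        assert inter.common_negative == {"g2"}
        assert inter.common_positive == set()

    def test_opposite_signs_excluded_and_reported(self):
        a = self._screen("suspension", pos=("g1",))
        b = self._screen("adhesion", neg=("g1",))
        inter = intersect_candidates([a, b])
        assert inter.common_positive == set() and inter.common_negative == set()
        assert inter.discordant == {"g1"}

    def test_empty_input_set_gives_empty_intersection(self):
        a = self._screen("suspension", pos=("g1", "g3"))
        b = self._screen("adhesion")
        inter = intersect_candidates([a, b])
        assert inter.common_positive == set()

    def test_adding_protocols_never_grows_intersection(self):
        a = self._screen("p1", pos=("g1", "g2"), neg=("g3",))
        b = self._screen("p2", pos=("g1",), neg=("g3",))
        c = self._screen("p3", pos=("g1",))
        two = intersect_candidates([a, b])
        three = intersect_candidates([a, b, c])
        assert three.common_positive <= two.common_positive
        assert three.common_negative <= two.common_negative

    def test_disjoint_universes_rejected(self):
        a = self._screen("p1", universe=("g1", "g2"))
        b = self._screen("p2", universe=("h1", "h2"))
        with pytest.raises(ValueError, match="universe"):
            intersect_candidates([a, b])

    def test_requires_two_results(self):
        with pytest.raises(ValueError):
            intersect_candidates([self._screen("p1")])

    def test_hand_built_exclusive_orderings(self):
        """Constructed orderings: one gene anti-monotone to a consensus of
        both protocols is the only sign-concordant survivor."""
        n = 10
        lines = [f"L{i:02d}" for i in range(n)]
        rank_a = {ln: i + 1 for i, ln in enumerate(lines)}
        # protocol B: two adjacent swaps away from A (sum d^2 = 4)
        order_b = lines.copy()
        order_b[0], order_b[1] = order_b[1], order_b[0]
        order_b[5], order_b[6] = order_b[6], order_b[5]
        rank_b = {ln: i + 1 for i, ln in enumerate(order_b)}
        prop_a = _propensity_from_ranks(rank_a, "suspension")
        prop_b = _propensity_from_ranks(rank_b, "adhesion")

        # shared gene: expression increases with rank position in A
        # (so r_s = -1 vs A, near -1 vs B); null genes: arbitrary noise
        rng = np.random.default_rng(1)
        means = pd.DataFrame(
            rng.normal(8, 1, size=(4, n)), columns=lines,
            index=["shared", "n1", "n2", "n3"],
        )
        means.loc["shared"] = [float(rank_a[ln]) for ln in lines]
        expr = _expression_from_line_means(means)
        res_a = screen_protocol(expr, prop_a)
        res_b = screen_protocol(expr, prop_b)
        inter = intersect_candidates([res_a, res_b])
        assert inter.common_negative == {"shared"}
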