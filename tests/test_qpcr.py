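import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from ctrlgenes import (
    CtTable,
    SyntheticConfig,
    correlation_validation,
    delta_ct,
    generate_ct_table,
    generate_dataset,
    relative_quantification,
    rq_panel,
    spearman_rho,
)


def brute_spearman(x, y):
    """Oracle: Pearson correlation of hand-computed average ranks."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


class TestDeltaCt:
    def test_simple_difference(self):
        assert delta_ct(25.0, 20.0) == 5.0

    def test_self_control_is_zero(self):
        assert delta_ct(23.4, 23.4) == 0.0

    def test_antisymmetry(self):
        assert delta_ct(25.0, 20.0) == -delta_ct(20.0, 25.0)

    def test_nan_propagates(self):
        assert np.isnan(delta_ct(np.nan, 20.0))


class TestRelativeQuantification:
    @pytest.mark.parametrize("ddct,rq", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
    def test_powers_of_two(self, ddct, rq):
        got_ddct, got_rq = relative_quantification(ddct, 0.0)
        assert got_ddct == ddct
        assert got_rq == rq

    def test_reciprocity(self):
        _, fwd = relative_quantification(3.7, 1.2)
        _, rev = relative_quantification(1.2, 3.7)
        assert fwd * rev == pytest.approx(1.0)

    def test_identity_holds_to_machine_precision(self, rng):
        for _ in range(200):
            d_s, d_c = rng.normal(0, 5, size=2)
            ddct, rq = relative_quantification(d_s, d_c)
            assert rq == 2.0 ** (-ddct)


class TestSpearman:
    def test_perfect_monotone_decrease(self):
        assert spearman_rho([1, 2, 3, 4], [10, 8, 3, 1]) == pytest.approx(-1.0)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 15))
            # small integer support forces ties
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            assert spearman_rho(x, y) == pytest.approx(brute_spearman(x, y))

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(1, 10, size=20)
        y = rng.uniform(1, 10, size=20)
        assert spearman_rho(np.exp(x), y) == pytest.approx(spearman_rho(x, y))

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(y, x))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])


def ct_table(rows, genes, samples=None):
    samples = samples or [f"s{j}" for j in range(len(rows[0]))]
    return CtTable(pd.DataFrame(rows, index=genes, columns=samples))


class TestRQPanel:
    def test_self_control_gives_unit_rq_everywhere(self):
        ct = ct_table([[24.0, 26.0, 28.0]], ["CD33"])
        panel = rq_panel(ct, "CD33", "CD33", ["s0"])
        assert all(r.rq == 1.0 for r in panel.results)
        assert panel.cv_percent == pytest.approx(0.0)
        assert panel.mfc == pytest.approx(1.0)

    def test_control_shift_leaves_rq_ratios_unchanged(self):
        rows = [[24.0, 25.0, 23.0], [20.0, 20.5, 19.5]]
        ct = ct_table(rows, ["tgt", "ctl"])
        shifted = ct_table(
            [rows[0], [c + 3.0 for c in rows[1]]], ["tgt", "ctl"]
        )
        p1 = rq_panel(ct, "tgt", "ctl", ["s0"])
        p2 = rq_panel(shifted, "tgt", "ctl", ["s0"])
        r1 = [r.rq for r in p1.results]
        r2 = [r.rq for r in p2.results]
        np.testing.assert_allclose(
            np.array(r1) / r1[0], np.array(r2) / r2[0]
        )
        assert p1.cv_percent == pytest.approx(p2.cv_percent)

    def test_noise_free_rq_cv_tracks_target_expression_cv(self):
        # with an exactly constant control and no Ct noise, RQ is
        # proportional to the target's RPKM, so RQ CV = expression CV
        cfg = SyntheticConfig(
            n_genes=50, n_samples=40, n_datasets=1, frac_stable=0.5,
            stable_cv_target=0.0, ct_noise_sd=0.0, seed=11,
        )
        from ctrlgenes import gene_universe, gene_stability

        m = generate_dataset(cfg, 0)
        uni = gene_universe(cfg)
        stable = uni.loc[uni["class"] == "stable", "gene_id"].iloc[0]
        variable = uni.loc[uni["class"] == "variable", "gene_id"].iloc[0]
        ct = generate_ct_table(m, cfg, [stable, variable])
        panel = rq_panel(
            ct, variable, stable, [m.sample_ids[0]], include_calibrator=True
        )
        true_cv = gene_stability(m.data.loc[variable], variable).cv_percent
        assert panel.cv_percent == pytest.approx(true_cv, rel=1e-9)

    def test_variable_control_inflates_rq_cv(self):
        cfg = SyntheticConfig(
            n_genes=60, n_samples=40, n_datasets=1, frac_stable=0.5,
            stable_cv_target=5.0, variable_cv_range=(80.0, 80.0),
            ct_noise_sd=0.0, seed=13,
        )
        from ctrlgenes import gene_universe

        m = generate_dataset(cfg, 0)
        uni = gene_universe(cfg)
        stable = uni.loc[uni["class"] == "stable", "gene_id"].tolist()
        variable = uni.loc[uni["class"] == "variable", "gene_id"].tolist()
        target = variable[0]
        ct = generate_ct_table(m, cfg, [target, stable[0], variable[1]])
        calib = [m.sample_ids[0]]
        good = rq_panel(ct, target, stable[0], calib)
        bad = rq_panel(ct, target, variable[1], calib)
        assert bad.cv_percent > good.cv_percent


class TestCorrelationValidation:
    def _setup(self, seed=3, ct_noise=0.0, control_cv=0.0):
        cfg = SyntheticConfig(
            n_genes=40, n_samples=15, n_datasets=1, frac_stable=0.5,
            stable_cv_target=control_cv, ct_noise_sd=ct_noise, seed=seed,
        )
        from ctrlgenes import gene_universe

        m = generate_dataset(cfg, 0)
        uni = gene_universe(cfg)
        stable = uni.loc[uni["class"] == "stable", "gene_id"].tolist()
        variable = uni.loc[uni["class"] == "variable", "gene_id"].tolist()
        return cfg, m, stable, variable

    def test_noise_free_constant_control_gives_rho_minus_one(self):
        cfg, m, stable, variable = self._setup()
        target = variable[0]
        ct = generate_ct_table(m, cfg, [target, stable[0]])
        reports = correlation_validation(m, ct, target, [stable[0]])
        assert reports[0].rho == pytest.approx(-1.0)
        assert reports[0].n == 15

    def test_variable_control_degrades_correlation(self):
        # mirror of the stable-vs-GAPDH-like contrast: an 80%-CV control
        # weakens |rho| relative to a 10%-CV control in >=95/100 replicates
        wins = 0
        for rep in range(100):
            cfg = SyntheticConfig(
                n_genes=10, n_samples=15, n_datasets=1, frac_stable=0.5,
                stable_cv_target=10.0, variable_cv_range=(80.0, 80.0),
                ct_noise_sd=0.25, seed=1000 + rep,
            )
            from ctrlgenes import gene_universe

            m = generate_dataset(cfg, 0)
            uni = gene_universe(cfg)
            stable = uni.loc[uni["class"] == "stable", "gene_id"].tolist()
            variable = uni.loc[uni["class"] == "variable", "gene_id"].tolist()
            target = variable[0]
            ct = generate_ct_table(m, cfg, [target, stable[0], variable[1]])
            reports = correlation_validation(
                m, ct, target, [stable[0], variable[1]]
            )
            rho = {r.control_gene_id: r.rho for r in reports}
            if abs(rho[stable[0]]) > abs(rho[variable[1]]):
                wins += 1
        assert wins >= 95

    def test_too_few_shared_samples_rejected(self):
        cfg, m, stable, variable = self._setup()
        ct = generate_ct_table(m, cfg, [variable[0], stable[0]])
        ct2 = CtTable(ct.data.iloc[:, :2])
        with pytest.raises(ValueError, match="shared"):
            correlation_validation(m, ct2, variable[0], [stable[0]])
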