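import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from canopycalib import (
    compute_w2,
    effective_dimension,
    fit_spatial_model,
    generate_design,
    nvt_spec,
    repeatability_trajectory,
)
from canopycalib.spatial import SpatialModel


def simulate_trial(seed, n_geno=30, n_reps=3, vg=4.0, vr=1.0, trend=0.0, mean=10.0):
    """Randomized row-column trial with known variance components."""
    rng = np.random.default_rng(seed)
    design = generate_design(nvt_spec(n_geno, n_reps), seed=seed)
    geff = {g: rng.normal(0, np.sqrt(vg)) for g in design.genotypes}
    n_cols = max(p.column for p in design.plots)
    rows = []
    for p in design.plots:
        sp = trend * np.sin(np.pi * p.column / n_cols) * np.cos(0.5 * np.pi * p.row / n_reps)
        rows.append({
            "row": p.row, "column": p.column, "genotype": p.genotype,
            "value": mean + geff[p.genotype] + sp + rng.normal(0, np.sqrt(vr)),
        })
    return pd.DataFrame(rows)


class TestREMLRecovery:
    def test_planted_variance_ratio_recovered(self):
        """V_G/V_R = 4 planted; median estimate within 30%."""
        vgs = [fit_spatial_model(simulate_trial(s)).v_g for s in range(100)]
        assert np.median(vgs) == pytest.approx(4.0, rel=0.30)

    def test_null_genotype_shrinks_to_zero(self):
        """With no genetic signal V_G sits at (or hugs) the REML boundary:
        per-seed estimates stay well below the residual variance and the
        typical fit is fully shrunken."""
        fits = [fit_spatial_model(simulate_trial(s, vg=0.0)) for s in range(20)]
        hits = sum((f.v_g < 0.25) for f in fits)  # a quarter of planted V_R
        assert hits >= 18
        assert np.median([f.v_g for f in fits]) < 0.01
        assert np.median([f.ed_genotype for f in fits]) < 0.1

    def test_translation_invariance(self):
        df = simulate_trial(3)
        a = fit_spatial_model(df)
        df2 = df.assign(value=df["value"] + 500.0)
        b = fit_spatial_model(df2)
        assert b.v_g == pytest.approx(a.v_g, rel=1e-3)
        assert b.v_r == pytest.approx(a.v_r, rel=1e-3)
        for k in a.effective_dims:
            assert b.effective_dims[k] == pytest.approx(a.effective_dims[k], abs=1e-3)

    def test_spatial_trend_does_not_inflate_vg(self):
        """A strong smooth field must be absorbed by the spline, not V_G."""
        base = np.median([fit_spatial_model(simulate_trial(s)).v_g for s in range(30)])
        trended = np.median([
            fit_spatial_model(simulate_trial(s, trend=4.0)).v_g for s in range(30)
        ])
        assert trended <= base * 1.2

    def test_inestimable_configurations_rejected(self):
        df = simulate_trial(1, n_geno=30, n_reps=1)
        with pytest.raises(ValueError, match="inestimable"):
            SpatialModel(df)
        one = simulate_trial(1).assign(genotype="G01")
        with pytest.raises(ValueError, match="2 genotypes"):
            SpatialModel(one)


class TestEffectiveDimensions:
    def test_ed_conservation(self):
        fit = fit_spatial_model(simulate_trial(5))
        total = fit.n_fixed + sum(fit.effective_dims.values()) + fit.ed_residual
        assert total == pytest.approx(len(fit.model.y))

    def test_fully_shrunk_genotype_has_zero_ed(self):
        model = SpatialModel(simulate_trial(2))
        res = model.results_at(np.array([-16.0, 0.0, 0.0, 0.0, 0.0]))
        assert res.effective_dims["genotype"] == pytest.approx(0.0, abs=1e-4)

    def test_unshrunk_genotype_approaches_fixed_effect_limit(self):
        """gamma_g -> inf: ED_g -> g - 1 (one dimension lost to the mean)."""
        df = simulate_trial(2, n_geno=10)
        model = SpatialModel(df)
        res = model.results_at(np.array([16.0, -10.0, -10.0, 10.0, 10.0]))
        assert res.effective_dims["genotype"] == pytest.approx(9.0, abs=0.2)

    def test_matches_dense_hat_matrix_trace(self):
        """12-plot instance: ED equals the trace of the explicitly assembled
        hat-matrix block (independent dense-matrix route)."""
        df = simulate_trial(7, n_geno=4, n_reps=3)
        assert len(df) == 12
        model = SpatialModel(df)
        theta = np.array([0.5, -0.5, 0.3, 1.0, 0.7])
        res = model.results_at(theta)

        X, Z = model.X, model._Z()
        W = np.hstack([X, Z])
        prec = model._prec_blocks(theta)
        P = np.zeros((W.shape[1], W.shape[1]))
        o = X.shape[1]
        for m in prec:
            P[o:o + m.shape[0], o:o + m.shape[0]] = m
            o += m.shape[0]
        Cinv = np.linalg.inv(W.T @ W + P)
        H = W @ Cinv @ W.T  # full hat matrix, assembled directly
        offs = np.cumsum([X.shape[1]] + list(model.block_sizes.values()))
        zblocks = [model.Z_g, model.Z_r, model.Z_c, model.Z_s]
        for k, name in enumerate(model.block_sizes):
            Hk = zblocks[k] @ Cinv[offs[k]:offs[k + 1], :] @ W.T
            assert res.effective_dims[name] == pytest.approx(np.trace(Hk), abs=1e-8)
        assert np.trace(H) == pytest.approx(
            model.X.shape[1] + sum(res.effective_dims.values()), abs=1e-8)

    def test_unknown_component_rejected(self):
        fit = fit_spatial_model(simulate_trial(1))
        with pytest.raises(KeyError):
            effective_dimension(fit, "block")
        assert effective_dimension(fit, "residual") == pytest.approx(fit.ed_residual)


class TestW2:
    def test_null_signal_w2_near_zero(self):
        fit = fit_spatial_model(simulate_trial(4, vg=0.0))
        assert compute_w2(fit) < 0.1

    def test_noiseless_limit_w2_near_one(self):
        fit = fit_spatial_model(simulate_trial(4, vg=4.0, vr=1e-4))
        assert compute_w2(fit) > 0.95

    def test_monotone_in_planted_heritability(self):
        med = []
        for h2 in (0.2, 0.5, 0.8):
            vals = [
                compute_w2(fit_spatial_model(simulate_trial(s, vg=h2, vr=1 - h2)))
                for s in range(15)
            ]
            med.append(np.median(vals))
        assert med[0] < med[1] < med[2]

    def test_always_in_unit_interval(self):
        for s in range(5):
            fit = fit_spatial_model(simulate_trial(s, vg=float(s), vr=0.5))
            assert 0.0 <= fit.w2() <= 1.0

    def test_printed_normalization_smaller(self):
        fit = fit_spatial_model(simulate_trial(6))
        assert fit.w2(as_printed=True) < fit.w2()


class TestAgainstLme4:
    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
    def test_variance_components_match_lme4(self, tmp_path):
        """Spline-free variant against the reference REML implementation."""
        df = simulate_trial(0, n_geno=15)
        fit = SpatialModel(df, include_spline=False).fit()
        csv = tmp_path / "trial.csv"
        df.to_csv(csv, index=False)
        script = f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
m <- lmer(value ~ 1 + (1|genotype) + (1|row) + (1|column), data=d, REML=TRUE)
vc <- as.data.frame(VarCorr(m))
out <- setNames(as.list(vc$vcov), vc$grp)
cat(jsonlite::toJSON(out, auto_unbox=TRUE))
"""
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True, timeout=120)
        assert proc.returncode == 0, proc.stderr
        ref = json.loads(proc.stdout)
        assert fit.v_g == pytest.approx(ref["genotype"], rel=0.02)
        assert fit.v_r == pytest.approx(ref["Residual"], rel=0.02)


class TestTrajectory:
    def _preds(self, seed, n_cuts=3, growth=1.0, n_exp=1):
        frames = []
        for e in range(n_exp):
            for cut in range(1, n_cuts + 1):
                df = simulate_trial(seed + 100 * e + cut, n_geno=10,
                                    vg=0.5 + growth * cut, vr=1.0,
                                    mean=100.0 * cut)
                df["experiment"] = f"E{e + 1}"
                df["cut_number"] = cut
                df = df.rename(columns={"value": "pred"})
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_one_row_per_experiment_cut_cell(self):
        table = repeatability_trajectory(self._preds(1, n_cuts=3, n_exp=2))
        assert len(table) == 6
        assert set(table["cut_number"]) == {1, 2, 3}

    def test_growing_genetic_signal_raises_vg_with_cut(self):
        slopes = []
        for seed in range(5):
            table = repeatability_trajectory(self._preds(seed, n_cuts=3, growth=3.0))
            slopes.append(np.polyfit(table["cut_number"], table["v_g"], 1)[0])
        assert np.median(slopes) > 0

    def test_identical_processes_give_similar_w2(self):
        diffs = []
        for seed in range(5):
            table = repeatability_trajectory(
                self._preds(seed, n_cuts=2, growth=0.0, n_exp=2))
            by_exp = table.groupby("experiment")["w2"].mean()
            diffs.append(abs(by_exp.iloc[0] - by_exp.iloc[1]))
        assert np.median(diffs) < 0.15

    def test_unfittable_cells_skipped_with_warning(self):
        preds = self._preds(1, n_cuts=2)
        bad = preds[preds["cut_number"] == 2].assign(genotype="G01")
        preds = pd.concat([preds[preds["cut_number"] == 1], bad])
        with pytest.warns(UserWarning, match="skipping"):
            table = repeatability_trajectory(preds)
        assert len(table) == 1
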