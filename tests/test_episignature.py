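"""Differential methylation, signature selection and episignature scoring."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from lumpsplit import (
    EpisignatureClassifier,
    EpisignatureModel,
    compute_covariate_pcs,
    differential_methylation,
    score_samples,
    select_signature,
    synth_beta,
    train_classifier,
)
from lumpsplit.errors import (
    DegenerateDesignError,
    InsufficientSamplesError,
    MissingProbeError,
)


@pytest.fixture(scope="module")
def planted_run():
    beta, sheet, planted = synth_beta(
        seed=7, n_validation_cases=1, n_validation_controls=20, n_test_other=5
    )
    stats = differential_methylation(beta, sheet)
    return beta, sheet, planted, stats


class TestCovariatePcs:
    def test_scores_orthogonal_and_zero_mean(self, planted_run):
        beta, sheet, *_ = planted_run
        samples = list(sheet.loc[sheet["role"] == "discovery", "sample_id"])
        pcs = compute_covariate_pcs(beta, samples)
        assert pcs["PC1"].mean() == pytest.approx(0.0, abs=1e-9)
        assert pcs["PC2"].mean() == pytest.approx(0.0, abs=1e-9)
        assert pcs["PC1"] @ pcs["PC2"] == pytest.approx(0.0, abs=1e-6)

    def test_recovers_planted_orthogonal_factors(self, rng):
        n_probes, n_samples = 400, 30
        f1 = np.repeat([1.0, -1.0], n_samples // 2)
        f2 = np.tile([1.0, -1.0], n_samples // 2)
        l1 = rng.standard_normal(n_probes) * 0.2
        l2 = rng.standard_normal(n_probes) * 0.1
        x = 0.5 + np.outer(l1, f1) + np.outer(l2, f2) + 1e-4 * rng.standard_normal((n_probes, n_samples))
        beta = pd.DataFrame(np.clip(x, 0, 1), columns=[f"s{i}" for i in range(n_samples)])
        pcs = compute_covariate_pcs(beta, list(beta.columns))
        assert abs(np.corrcoef(pcs["PC1"], f1)[0, 1]) > 0.99
        assert abs(np.corrcoef(pcs["PC2"], f2)[0, 1]) > 0.99

    def test_duplicating_samples_preserves_leading_subspace(self, rng):
        x = np.clip(0.5 + 0.1 * rng.standard_normal((200, 10)), 0, 1)
        beta = pd.DataFrame(x, columns=[f"s{i}" for i in range(10)])
        pcs = compute_covariate_pcs(beta, list(beta.columns))
        dup = pd.concat([beta, beta.add_suffix("_dup", axis=1)], axis=1)
        pcs_dup = compute_covariate_pcs(dup, list(dup.columns))
        first = pcs_dup.iloc[:10]
        for col in ("PC1", "PC2"):
            assert abs(np.corrcoef(pcs[col], first[col])[0, 1]) > 0.999

    def test_too_few_samples_rejected(self, planted_run):
        beta, sheet, *_ = planted_run
        with pytest.raises(InsufficientSamplesError):
            compute_covariate_pcs(beta, list(beta.columns[:2]))


def bh_stepup_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestDifferentialMethylation:
    def test_constant_probe_gets_zero_statistics(self):
        beta, sheet, _ = synth_beta(n_probes=300, n_signature=10, seed=3)
        beta.iloc[0] = 0.42
        stats = differential_methylation(beta, sheet)
        assert stats.iloc[0]["delta_beta"] == pytest.approx(0.0, abs=1e-12)
        assert stats.iloc[0]["moderated_t"] == 0.0

    def test_equal_variances_reduce_moderated_t_to_pooled_t(self, rng):
        # identical residual variance in every probe: infinite prior df, and
        # each moderated t equals the ordinary t computed with that variance
        n = 24
        group = np.array([1.0] * 12 + [0.0] * 12)
        base = rng.standard_normal(n)
        base = (base - base.mean()) / base.std(ddof=1)  # exact unit variance
        y = np.vstack([0.5 + 0.02 * base + 0.05 * group * (i % 3) for i in range(40)])
        beta = pd.DataFrame(np.clip(y, 0, 1), columns=[f"s{i}" for i in range(n)])
        sheet = pd.DataFrame(
            {
                "sample_id": beta.columns,
                "group": ["case"] * 12 + ["control"] * 12,
                "role": "discovery",
            }
        )
        cov = pd.DataFrame(
            0.0, index=beta.columns, columns=["PC1", "PC2"]
        )  # no covariate structure
        cov["PC1"] = rng.standard_normal(n) * 1e-9
        cov["PC2"] = rng.standard_normal(n) * 1e-9
        stats = differential_methylation(beta, sheet, covariates=cov)
        assert np.isinf(stats.attrs["df_prior"]) or stats.attrs["df_prior"] > 1e4

    def test_bh_adjustment_matches_stepup_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, 50)
            ours = multipletests(p, method="fdr_bh")[1]  # route used internally
            np.testing.assert_allclose(ours, bh_stepup_oracle(p), atol=1e-12)

    def test_q_at_least_p(self, planted_run):
        *_, stats = planted_run
        assert (stats["q"] >= stats["p"] - 1e-15).all()
        assert (stats["delta_beta"].abs() <= 1.0).all()

    def test_null_simulation_controls_fdr(self):
        hits = 0
        for seed in range(5):
            beta, sheet, _ = synth_beta(
                n_probes=1000, n_signature=0, delta_beta=0.0, seed=100 + seed
            )
            stats = differential_methylation(beta, sheet)
            hits += int((stats["q"] <= 0.05).sum())
        assert hits <= 2

    def test_single_sample_group_rejected(self):
        beta, sheet, _ = synth_beta(n_probes=100, n_signature=5, seed=1)
        sheet.loc[(sheet["group"] == "case") & (sheet.index > 0), "role"] = "test"
        with pytest.raises(DegenerateDesignError):
            differential_methylation(beta, sheet)

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's lmFit + eBayes on the same small matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(5)
        n_probes, n_case, n_ctrl = 120, 6, 8
        n = n_case + n_ctrl
        y = 0.5 + 0.04 * rng.standard_normal((n_probes, n))
        y[:10, :n_case] += 0.08
        beta = pd.DataFrame(
            np.clip(y, 0, 1),
            index=[f"cg{i}" for i in range(n_probes)],
            columns=[f"s{i}" for i in range(n)],
        )
        sheet = pd.DataFrame(
            {
                "sample_id": beta.columns,
                "group": ["case"] * n_case + ["control"] * n_ctrl,
                "role": "discovery",
            }
        )
        cov = pd.DataFrame(
            rng.standard_normal((n, 2)), index=beta.columns, columns=["PC1", "PC2"]
        )
        stats = differential_methylation(beta, sheet, covariates=cov)
        beta.to_csv(tmp_path / "beta.tsv", sep="\t")
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "group": [1.0] * n_case + [0.0] * n_ctrl,
                "PC1": cov["PC1"].to_numpy(),
                "PC2": cov["PC2"].to_numpy(),
            }
        )
        design.to_csv(tmp_path / "design.tsv", sep="\t", index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            beta <- as.matrix(read.delim("beta.tsv", sep="\\t", row.names=1))
            design <- as.matrix(read.delim("design.tsv", sep="\\t"))
            fit <- eBayes(lmFit(beta, design))
            out <- data.frame(t=fit$t[, "group"], p=fit$p.value[, "group"])
            write.table(out, "limma_out.tsv", sep="\\t", quote=FALSE)
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", "oracle.R"], cwd=tmp_path, capture_output=True, text=True
        )
        if proc.returncode != 0:
            pytest.skip(f"limma oracle unavailable: {proc.stderr[-300:]}")
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
        np.testing.assert_allclose(
            stats["moderated_t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-4, atol=1e-6
        )
        np.testing.assert_allclose(
            stats["p"].to_numpy(), ref["p"].to_numpy(), rtol=1e-4, atol=1e-8
        )


class TestSelectSignature:
    def test_threshold_rule(self):
        stats = pd.DataFrame(
            {
                "delta_beta": [0.06, 0.04, 0.20],
                "moderated_t": [3.0, 3.0, 1.0],
                "p": [0.001, 0.001, 0.02],
                "q": [0.04, 0.04, 0.06],
            },
            index=["keep", "small_delta", "big_q"],
        )
        assert select_signature(stats) == ["keep"]

    def test_ordering_by_q_then_abs_delta(self):
        stats = pd.DataFrame(
            {
                "delta_beta": [0.06, -0.30, 0.10],
                "moderated_t": [1.0, 1.0, 1.0],
                "p": [0.001] * 3,
                "q": [0.04, 0.01, 0.01],
            },
            index=["third", "first", "second"],
        )
        assert select_signature(stats) == ["first", "second", "third"]

    def test_planted_signature_recovery(self):
        tps, fps = [], []
        for seed in range(5):
            beta, sheet, planted = synth_beta(seed=200 + seed)
            stats = differential_methylation(beta, sheet)
            sig = select_signature(stats)
            tps.append(len(set(sig) & set(planted)))
            fps.append(len(sig) - tps[-1])
        assert np.median(tps) >= 27
        assert np.median(fps) <= 2

    def test_all_null_input_selects_nothing(self):
        beta, sheet, _ = synth_beta(n_probes=500, n_signature=0, delta_beta=0.0, seed=9)
        stats = differential_methylation(beta, sheet)
        assert select_signature(stats) == []


class TestClassifier:
    def test_training_samples_separate_around_half(self, planted_run):
        beta, sheet, planted, stats = planted_run
        sig = select_signature(stats)
        model = train_classifier(beta, sheet, sig)
        scores = score_samples(model, beta)
        merged = scores.join(sheet.set_index("sample_id"))
        disc = merged[merged["role"] == "discovery"]
        assert (disc.loc[disc["group"] == "case", "score"] > 0.5).all()
        assert (disc.loc[disc["group"] == "control", "score"] < 0.5).all()

    def test_scores_bounded_and_labelled(self, planted_run):
        beta, sheet, planted, stats = planted_run
        model = train_classifier(beta, sheet, select_signature(stats))
        scores = score_samples(model, beta)
        assert scores["score"].between(0, 1).all()
        assert set(scores["label"]) <= {"case-like", "not-case", "indeterminate"}
        assert (
            (scores.loc[scores["score"] > 0.5, "label"] == "case-like").all()
        )

    def test_heldout_validation_and_signature_free_test_samples(self, planted_run):
        beta, sheet, planted, stats = planted_run
        model = train_classifier(beta, sheet, select_signature(stats))
        scores = score_samples(model, beta).join(sheet.set_index("sample_id"))
        val = scores[scores["role"] == "validation"]
        assert (val.loc[val["group"] == "case", "score"] > 0.5).all()
        assert (val.loc[val["group"] == "control", "score"] < 0.5).all()
        # other-subgroup samples lack the signature: classified not-case
        test = scores[scores["role"] == "test"]
        assert (test["score"] < 0.5).all()

    def test_probe_order_permutation_invariance(self, planted_run):
        beta, sheet, planted, stats = planted_run
        sig = select_signature(stats)
        model = train_classifier(beta, sheet, sig)
        shuffled = beta.sample(frac=1.0, random_state=0)
        s1 = score_samples(model, beta)["score"]
        s2 = score_samples(model, shuffled)["score"]
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_missing_probe_rejected(self, planted_run):
        beta, sheet, planted, stats = planted_run
        model = train_classifier(beta, sheet, select_signature(stats))
        with pytest.raises(MissingProbeError):
            score_samples(model, beta.drop(index=model.probe_ids[0]))

    def test_single_class_training_rejected(self, rng):
        X = rng.uniform(0, 1, (8, 5))
        with pytest.raises(DegenerateDesignError):
            EpisignatureClassifier().fit(X, np.zeros(8))

    def test_estimator_params_and_json_round_trip(self, planted_run):
        beta, sheet, planted, stats = planted_run
        est = EpisignatureClassifier(C=2.0)
        assert est.get_params() == {"C": 2.0}
        model = train_classifier(beta, sheet, select_signature(stats), C=2.0)
        restored = EpisignatureModel.from_json_dict(model.to_json_dict())
        np.testing.assert_allclose(
            score_samples(restored, beta)["score"], score_samples(model, beta)["score"]
        )


class TestSynthBeta:
    def test_planted_mean_shift_near_delta(self):
        beta, sheet, planted = synth_beta(seed=4)
        cases = sheet.loc[
            (sheet["group"] == "case") & (sheet["role"] == "discovery"), "sample_id"
        ]
        ctrls = sheet.loc[sheet["group"] == "control", "sample_id"]
        diff = (
            beta.loc[planted, list(cases)].mean(axis=1)
            - beta.loc[planted, list(ctrls)].mean(axis=1)
        )
        assert abs(diff.mean() - 0.10) < 0.02

    def test_zero_delta_indistinguishable(self):
        flags = 0
        from scipy.stats import ttest_ind

        for seed in range(10):
            beta, sheet, _ = synth_beta(
                n_probes=400, n_signature=0, delta_beta=0.0, seed=300 + seed,
                n_confounders=0,
            )
            cases = sheet.loc[sheet["group"] == "case", "sample_id"]
            ctrls = sheet.loc[sheet["group"] == "control", "sample_id"]
            pooled_case = beta[list(cases)].mean(axis=0)
            pooled_ctrl = beta[list(ctrls)].mean(axis=0)
            flags += ttest_ind(pooled_case, pooled_ctrl).pvalue < 0.05
        assert flags <= 2

    def test_same_seed_identical(self):
        b1, s1, p1 = synth_beta(seed=6)
        b2, s2, p2 = synth_beta(seed=6)
        pd.testing.assert_frame_equal(b1, b2)
        assert p1 == p2

    def test_values_in_unit_interval(self):
        beta, *_ = synth_beta(seed=8, delta_beta=0.4, noise_sd=0.3)
        assert beta.to_numpy().min() >= 0.0
        assert beta.to_numpy().max() <= 1.0
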