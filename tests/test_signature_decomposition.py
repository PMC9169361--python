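import numpy as np
import pytest

from apobecmut.signature_decomposition import (
    ContextMatrix96,
    ReferenceCatalog,
    SignatureSet,
    annotate_signatures,
    build_context_matrix,
    cosine_similarity,
    extract_signatures,
    fit_exposures_nnls,
    select_rank,
)
from apobecmut.synthetic_data import (
    gen_reference,
    plant_mutations,
    planted_exposures,
    sim_signature_counts,
    synthetic_sbs_catalog,
)
from apobecmut.variant_io import CHANNEL_LABELS, MutationTable, attach_context

from .conftest import make_record
from .oracles import naive_channel_counts, nnls_oracle


class TestBuildContextMatrix:
    def test_single_snv_lands_in_its_channel(self):
        table = MutationTable([make_record("TCA", "C", "T")])
        mat = build_context_matrix(table)
        assert mat.counts.sum() == 1
        assert mat.to_frame().loc["S1", "T[C>T]A"] == 1

    def test_strand_mirror_increments_same_channel(self):
        table = MutationTable(
            [make_record("TGA", "G", "A"), make_record("TCA", "C", "T")]
        )
        mat = build_context_matrix(table)
        assert mat.to_frame().loc["S1", "T[C>T]A"] == 2

    def test_matches_naive_rescan_and_row_sums(self):
        ref = gen_reference(5_000, 0.5, seed=13)
        muts, _ = plant_mutations(ref, 4, 250, 0.3, seed=14)
        table = attach_context(muts, ref)
        mat = build_context_matrix(table)
        expected, skipped = naive_channel_counts(table.records)
        frame = mat.to_frame()
        for label in CHANNEL_LABELS:
            assert frame[label].sum() == expected[label]
        assert mat.n_excluded == skipped
        per_sample = {s: 0 for s in table.sample_ids}
        for rec in table:
            from apobecmut.variant_io import try_normalize

            if try_normalize(rec) is not None:
                per_sample[rec.sample_id] += 1
        assert list(frame.sum(axis=1)) == [per_sample[s] for s in table.sample_ids]

    def test_excluded_records_tallied(self):
        recs = [
            make_record("TCA", "C", "T"),
            make_record("NCA", "C", "T"),  # N context
            make_record(None, "C", "T"),  # no context
        ]
        mat = build_context_matrix(MutationTable(recs))
        assert mat.counts.sum() == 1
        assert mat.n_excluded == 2

    def test_strand_invariance_of_simulated_genome(self):
        """Reverse-complementing the genome and alleles leaves the matrix unchanged."""
        from apobecmut.variant_io import reverse_complement

        ref = gen_reference(3_000, 0.5, seed=15)
        muts, _ = plant_mutations(ref, 3, 120, 0.5, seed=16)
        table = attach_context(muts, ref)
        fwd = build_context_matrix(table).to_frame()

        L = len(ref["chr1"])
        rc_ref = {"chr1": reverse_complement(ref["chr1"])}
        flipped = MutationTable(
            [
                make_record(
                    None,
                    reverse_complement(r.ref_allele),
                    reverse_complement(r.alt_allele),
                    sample=r.sample_id,
                    pos=L - r.pos + 1,
                )
                for r in muts
            ]
        )
        rev = build_context_matrix(attach_context(flipped, rc_ref)).to_frame()
        assert (fwd.to_numpy() == rev.to_numpy()).all()


class TestExtractSignatures:
    def test_planted_profiles_recovered(self):
        cat = synthetic_sbs_catalog()
        P = cat.profiles[["SBS_APOBEC_CT", "SBS_CPG_CT", "SBS_TG"]].to_numpy()
        H, _ = planted_exposures(40, 3, 2_000, seed=21)
        mat = sim_signature_counts(P, H, seed=22)
        sigs = extract_signatures(mat, [3], restarts=5, seed=23)[3]
        # greedy cosine matching, best pair first
        sims = np.array(
            [
                [cosine_similarity(sigs.profiles[:, i], P[:, j]) for j in range(3)]
                for i in range(3)
            ]
        )
        matched = []
        work = sims.copy()
        for _ in range(3):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            matched.append(work[i, j])
            work[i, :] = -1
            work[:, j] = -1
        assert min(matched) >= 0.9

    def test_rank_one_degenerate_case(self):
        cat = synthetic_sbs_catalog()
        P = cat.profiles[["SBS_FLAT"]].to_numpy()
        H = np.full((12, 1), 1_000)
        mat = sim_signature_counts(P, H, seed=24)
        sigs = extract_signatures(mat, [1], restarts=3, seed=25)[1]
        assert sigs.cophenetic == 1.0
        assert cosine_similarity(sigs.profiles[:, 0], P[:, 0]) > 0.99

    def test_same_seed_is_bit_identical(self):
        cat = synthetic_sbs_catalog()
        P = cat.profiles[["SBS_APOBEC_CT", "SBS_FLAT"]].to_numpy()
        H, _ = planted_exposures(15, 2, 500, seed=26)
        mat = sim_signature_counts(P, H, seed=27)
        a = extract_signatures(mat, [2], restarts=3, seed=28)[2]
        b = extract_signatures(mat, [2], restarts=3, seed=28)[2]
        assert (a.profiles == b.profiles).all()
        assert a.cophenetic == b.cophenetic

    def test_permutation_equivariance(self):
        """Permuting sample rows leaves profiles unchanged (same seed)."""
        cat = synthetic_sbs_catalog()
        P = cat.profiles[["SBS_APOBEC_CT", "SBS_CPG_CT"]].to_numpy()
        H, _ = planted_exposures(12, 2, 800, seed=29)
        mat = sim_signature_counts(P, H, seed=30)
        perm = np.random.default_rng(31).permutation(12)
        mat_perm = ContextMatrix96(
            mat.counts[perm], [mat.sample_ids[i] for i in perm]
        )
        sigs = extract_signatures(mat, [2], restarts=4, seed=32)[2]
        exp = fit_exposures_nnls(mat, sigs).exposures
        exp_perm = fit_exposures_nnls(mat_perm, sigs).exposures
        assert np.allclose(exp[perm], exp_perm)

    def test_too_large_rank_rejected(self):
        mat = ContextMatrix96(np.ones((5, 96)), [f"S{i}" for i in range(5)])
        with pytest.raises(ValueError):
            extract_signatures(mat, [6], restarts=2, seed=0)


class TestSelectRank:
    def test_first_significant_drop(self):
        assert select_rank({2: 0.99, 3: 0.98, 4: 0.80, 5: 0.78}) == 3

    def test_flat_profile_falls_back_to_argmax_smallest(self):
        assert select_rank({2: 0.95, 3: 0.95, 4: 0.94}) == 2

    def test_single_rank_warns(self):
        with pytest.warns(UserWarning):
            assert select_rank({4: 0.7}) == 4


class TestAnnotate:
    def test_identity_match(self):
        cat = synthetic_sbs_catalog()
        sigs = SignatureSet(cat.profiles[["SBS_APOBEC_CT"]].to_numpy())
        ann = annotate_signatures(sigs, cat).annotations
        assert ann[0].name == "SBS_APOBEC_CT"
        assert ann[0].cosine == 1.0

    def test_disjoint_support_unassigned(self):
        labels = list(CHANNEL_LABELS)
        cat_profile = np.zeros(96)
        cat_profile[:16] = 1 / 16  # C>A block only
        import pandas as pd

        cat = ReferenceCatalog(pd.DataFrame({"CA_ONLY": cat_profile}, index=labels))
        sig_profile = np.zeros(96)
        sig_profile[80:] = 1 / 16  # T>G block only
        ann = annotate_signatures(SignatureSet(sig_profile[:, None]), cat).annotations
        assert ann[0].name == "unassigned"
        assert ann[0].cosine == 0.0

    def test_noisy_copy_recovered_and_cosine_exact(self):
        cat = synthetic_sbs_catalog()
        P = cat.profiles[["SBS_CPG_CT"]].to_numpy()
        counts = sim_signature_counts(P, np.full((1, 1), 2_000), seed=33).counts[0]
        noisy = counts / counts.sum()
        ann = annotate_signatures(SignatureSet(noisy[:, None]), cat).annotations
        assert ann[0].name == "SBS_CPG_CT"
        # cosine agrees with an independent dot-product computation
        all_cos = {
            name: float(
                np.dot(noisy, cat.profiles[name])
                / (np.linalg.norm(noisy) * np.linalg.norm(cat.profiles[name]))
            )
            for name in cat.names
        }
        assert ann[0].cosine == pytest.approx(max(all_cos.values()), abs=5e-4)


class TestNnlsExposures:
    def test_exact_recovery_of_noiseless_mixture(self):
        cat = synthetic_sbs_catalog()
        P = cat.profiles[["SBS_APOBEC_CT", "SBS_CPG_CT", "SBS_FLAT"]].to_numpy()
        h_true = np.array([300.0, 150.0, 50.0])
        v = P @ h_true
        mat = ContextMatrix96(v[None, :], ["S1"])
        fit = fit_exposures_nnls(mat, SignatureSet(P))
        assert np.linalg.norm(fit.exposures[0] - h_true) / np.linalg.norm(
            h_true
        ) < 1e-6

    def test_orthogonal_sample_gets_zero_exposure(self):
        P = np.zeros((96, 1))
        P[:16, 0] = 1 / 16  # C>A support only
        v = np.zeros(96)
        v[90] = 10.0  # T>G channel
        mat = ContextMatrix96(v[None, :], ["S1"])
        fit = fit_exposures_nnls(mat, SignatureSet(P))
        assert fit.exposures[0, 0] == 0.0
        assert fit.residual[0] == pytest.approx(np.linalg.norm(v))

    def test_zero_count_sample(self):
        cat = synthetic_sbs_catalog()
        P = cat.profiles[["SBS_FLAT"]].to_numpy()
        mat = ContextMatrix96(np.zeros((1, 96)), ["S1"])
        fit = fit_exposures_nnls(mat, SignatureSet(P))
        assert fit.exposures[0, 0] == 0.0 and fit.residual[0] == 0.0

    def test_agrees_with_bvls_oracle_on_noisy_samples(self):
        cat = synthetic_sbs_catalog()
        cols = ["SBS_APOBEC_CT", "SBS_APOBEC_CG", "SBS_CPG_CT", "SBS_FLAT"]
        P = cat.profiles[cols].to_numpy()
        H, _ = planted_exposures(20, 4, 1_000, seed=34)
        mat = sim_signature_counts(P, H, seed=35)
        fit = fit_exposures_nnls(mat, SignatureSet(P))
        for i in range(mat.n_samples):
            expected = nnls_oracle(P, mat.counts[i].astype(float))
            assert np.allclose(fit.exposures[i], expected, atol=1e-8)

    def test_reconstruction_error_weakly_decreases_with_rank(self):
        cat = synthetic_sbs_catalog()
        P = cat.profiles[["SBS_APOBEC_CT", "SBS_CPG_CT", "SBS_TG"]].to_numpy()
        H, _ = planted_exposures(30, 3, 1_500, seed=36)
        mat = sim_signature_counts(P, H, seed=37)
        sigsets = extract_signatures(mat, range(1, 5), restarts=4, seed=38)
        errs = []
        for k in sorted(sigsets):
            fit = fit_exposures_nnls(mat, sigsets[k])
            errs.append(float(np.sum(fit.residual**2)))
        assert all(a >= b - 1e-6 for a, b in zip(errs, errs[1:]))


class TestReferenceCatalog:
    def test_tsv_round_trip(self, tmp_path):
        cat = synthetic_sbs_catalog()
        path = tmp_path / "catalog.tsv"
        cat.to_tsv(path)
        back = ReferenceCatalog.from_tsv(path)
        assert back.names == cat.names
        assert np.allclose(back.profiles.to_numpy(), cat.profiles.to_numpy())

    def test_non_stochastic_catalog_rejected(self):
        import pandas as pd

        bad = pd.DataFrame({"X": np.full(96, 0.02)}, index=list(CHANNEL_LABELS))
        with pytest.raises(ValueError):
            ReferenceCatalog(bad)
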