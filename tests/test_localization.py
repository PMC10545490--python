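"""Heatmap averaging, longitudinal profiles, and μ/σ fitting."""

import numpy as np
import pytest

from cardiopair.localization import (
    Profile,
    average_heatmap,
    compare_timecourse,
    fit_localization,
    longitudinal_profile,
)
from cardiopair.registration import StandardizedPair

from conftest import make_standardized


class TestAverageHeatmap:
    def test_mean_of_identical_pairs_is_the_normalized_pair(self, standardized_pair):
        hm = average_heatmap([standardized_pair] * 5, "junction")
        raster = standardized_pair.channels["junction"]
        norm = (raster - raster.min()) / (raster.max() - raster.min())
        np.testing.assert_allclose(hm.data, norm, atol=1e-12)
        assert hm.n_pairs == 5

    def test_pair_plus_mirror_is_symmetric(self, standardized_pair):
        hm = average_heatmap(
            [standardized_pair, standardized_pair.mirrored()], "junction"
        )
        np.testing.assert_allclose(hm.data, hm.data[:, ::-1], atol=1e-12)

    def test_mixed_grid_shapes_rejected(self, standardized_pair):
        other = StandardizedPair(
            channels={"junction": np.zeros((32, 256))},
            geometry=standardized_pair.geometry,
        )
        with pytest.raises(ValueError, match="mixed"):
            average_heatmap([standardized_pair, other], "junction")

    def test_averaging_suppresses_noise_like_sqrt_n(self, clean_spec):
        """Off-band residual SD of a 20-pair average drops ≈ √20."""
        noisy = clean_spec.with_(noise_sd=0.1)
        pairs = [make_standardized(noisy.with_(seed=100 + i)) for i in range(20)]
        hm20 = average_heatmap(pairs, "junction")
        hm1 = average_heatmap(pairs[:1], "junction")
        off_band = np.abs(pairs[0].x_coords) > 0.5
        ratio = hm1.data[:, off_band].std() / hm20.data[:, off_band].std()
        assert ratio == pytest.approx(np.sqrt(20), rel=0.25)


class TestLongitudinalProfile:
    def test_junctional_mass_concentrates_at_d_one(self, standardized_pair):
        prof = longitudinal_profile(standardized_pair, "junction")
        mass_near_junction = np.trapezoid(
            prof.density[prof.d > 0.8], prof.d[prof.d > 0.8]
        )
        assert mass_near_junction > 0.95

    def test_diffuse_profile_is_flat(self, clean_spec):
        sp = make_standardized(
            clean_spec.with_(junctional_weight=0.0, diffuse_weight=1.0)
        )
        prof = longitudinal_profile(sp, "junction")
        interior = (prof.d > 0.05) & (prof.d < 0.95)
        cv = prof.density[interior].std() / prof.density[interior].mean()
        assert cv < 0.05

    def test_perinuclear_distribution_centred_at_nuclear_position(self, clean_spec):
        """Nuclei centred at |x| = 0.5 put the perinuclear centre at d ≈ 0.5.

        The transversely integrated annulus is limb-brightened (local
        maxima at the ring edges), so the centre is read from the fitted
        Gaussian, which straddles both limbs symmetrically.
        """
        sp = make_standardized(
            clean_spec.with_(junctional_weight=0.0, perinuclear_weight=1.0,
                             nuclear_offset_frac=0.5)
        )
        prof = longitudinal_profile(sp, "junction")
        res = fit_localization(prof)
        assert res.mu == pytest.approx(0.5, abs=0.03)
        # and the raw profile mass is concentrated around the nucleus
        mass_near = np.trapezoid(prof.density[np.abs(prof.d - 0.5) < 0.2],
                                 prof.d[np.abs(prof.d - 0.5) < 0.2])
        assert mass_near > 0.9

    def test_zero_intensity_raises(self, standardized_pair):
        sp = StandardizedPair(
            channels={"junction": np.zeros(standardized_pair.shape)},
            geometry=standardized_pair.geometry,
        )
        with pytest.raises(ValueError, match="zero total intensity"):
            longitudinal_profile(sp, "junction")


class TestFitLocalization:
    def test_recovers_noiseless_gaussian(self):
        d = np.linspace(0.002, 0.998, 256)
        dens = np.exp(-((d - 0.9) ** 2) / (2 * 0.05**2))
        dens /= np.trapezoid(dens, d)
        res = fit_localization(Profile(d=d, density=dens))
        assert not res.fallback
        assert res.mu == pytest.approx(0.9, abs=1e-3)
        assert res.sigma == pytest.approx(0.05, abs=1e-3)

    def test_flat_profile_falls_back_to_uniform_moments(self):
        d = np.linspace(0.002, 0.998, 256)
        res = fit_localization(Profile(d=d, density=np.ones_like(d)))
        assert res.fallback
        assert res.mu == pytest.approx(0.5, abs=1e-3)
        assert res.sigma == pytest.approx(1 / np.sqrt(12), abs=0.005)

    def test_mu_nonincreasing_along_junctional_to_diffuse_sweep(self, clean_spec):
        mus = []
        for wj in (1.0, 0.75, 0.5, 0.25, 0.0):
            sp = make_standardized(
                clean_spec.with_(junctional_weight=wj, diffuse_weight=1.0 - wj)
            )
            mus.append(fit_localization(longitudinal_profile(sp, "junction")).mu)
        assert all(a >= b - 1e-6 for a, b in zip(mus, mus[1:]))
        assert mus[0] > mus[-1] + 0.3

    def test_phenotype_classes_strictly_ordered(self, clean_spec):
        """μ: junctional > diffuse > perinuclear (the disease-readout order)."""
        mu = {}
        for name, w in {
            "junctional": (1.0, 0.0, 0.0),
            "diffuse": (0.0, 1.0, 0.0),
            "perinuclear": (0.0, 0.0, 1.0),
        }.items():
            sp = make_standardized(clean_spec.with_(
                junctional_weight=w[0], diffuse_weight=w[1],
                perinuclear_weight=w[2],
            ))
            mu[name] = fit_localization(longitudinal_profile(sp, "junction")).mu
        assert mu["junctional"] > mu["diffuse"] > mu["perinuclear"]

    def test_scale_invariance_of_mu_sigma(self, standardized_pair):
        ref = fit_localization(longitudinal_profile(standardized_pair, "junction"))
        scaled = StandardizedPair(
            channels={k: 13.7 * v for k, v in standardized_pair.channels.items()},
            geometry=standardized_pair.geometry,
        )
        res = fit_localization(longitudinal_profile(scaled, "junction"))
        assert res.mu == pytest.approx(ref.mu, abs=1e-9)
        assert res.sigma == pytest.approx(ref.sigma, abs=1e-9)

    def test_mirror_gives_identical_result(self, clean_spec):
        sp = make_standardized(clean_spec.with_(band_offset=10.0))
        a = fit_localization(longitudinal_profile(sp, "junction"))
        b = fit_localization(longitudinal_profile(sp.mirrored(), "junction"))
        assert a.mu == pytest.approx(b.mu, abs=1e-12)
        assert a.sigma == pytest.approx(b.sigma, abs=1e-12)

    @pytest.mark.parametrize("offset_um, sigma_um", [
        (0.0, 3.0), (0.0, 6.0), (10.0, 4.0), (20.0, 6.0), (30.0, 4.0),
    ])
    def test_band_parameter_recovery_noise_free(self, clean_spec, offset_um, sigma_um):
        spec = clean_spec.with_(band_offset=offset_um,
                                junction_band_sigma=sigma_um)
        sp = make_standardized(spec)
        res = fit_localization(longitudinal_profile(sp, "junction"))
        half_len = spec.geometry.length / 2
        assert res.mu == pytest.approx(1 - offset_um / half_len, abs=0.02)
        assert res.sigma == pytest.approx(sigma_um / half_len, abs=0.02)


class TestCompareTimecourse:
    def _records(self, genotype, day, mu, sigma, n=4):
        return [
            {"genotype": genotype, "treatment": "veh", "day": day,
             "protein": "CX43", "mu": mu + 0.001 * i, "sigma": sigma}
            for i in range(n)
        ]

    def test_identical_groups_identical_summaries(self):
        recs = self._records("WT", 9, 0.9, 0.05) + self._records("ACM", 9, 0.9, 0.05)
        out = compare_timecourse(recs)
        wt = out[out.genotype == "WT"].iloc[0]
        acm = out[out.genotype == "ACM"].iloc[0]
        assert wt.mu_mean == pytest.approx(acm.mu_mean)
        assert wt.n == acm.n == 4

    def test_junctional_vs_diffuse_cohorts_separate(self, clean_spec):
        recs = []
        for i in range(4):
            for geno, weights in (("WT", (1.0, 0.0)), ("ACM", (0.0, 1.0))):
                sp = make_standardized(clean_spec.with_(
                    seed=200 + i, junctional_weight=weights[0],
                    diffuse_weight=weights[1],
                ))
                res = fit_localization(longitudinal_profile(sp, "junction"))
                recs.append({"genotype": geno, "treatment": "veh", "day": 9,
                             "protein": "PKP2", "mu": res.mu, "sigma": res.sigma})
        out = compare_timecourse(recs)
        d_mu = (out[out.genotype == "WT"].mu_mean.iloc[0]
                - out[out.genotype == "ACM"].mu_mean.iloc[0])
        assert d_mu > 0.3

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError, match="missing fields"):
            compare_timecourse([{"genotype": "WT", "mu": 1.0}])
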