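"""System enumeration, domain-gated screening and the AC map."""

import numpy as np
import pytest

from sigscreen.domain import fit_ad
from sigscreen.screening import (
    ScreeningResult,
    ac_map,
    enumerate_systems,
    results_frame,
    screen,
)


class TestEnumerate:
    def test_two_solvents_six_compositions(self, library):
        lib = {k: library[k] for k in ("water", "methanol")}
        enum = enumerate_systems(lib, [("methanol", "water")])
        assert len(enum) == 6  # 4 intermediate + 2 neat endpoints
        assert enum.n_pair_composition == 6
        neat = [s for s in enum if s.solvent_b is None]
        assert {s.solvent_a for s in neat} == {"water", "methanol"}

    def test_empty_whitelist_gives_neats_only(self, library):
        lib = {k: library[k] for k in ("water", "methanol", "DMSO")}
        enum = enumerate_systems(lib, [])
        assert len(enum) == 3
        assert all(s.solvent_b is None for s in enum)

    def test_both_counting_conventions_reported(self, library):
        names = list(library)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        enum = enumerate_systems(library, pairs)
        assert enum.n_pair_composition == len(pairs) * 6
        # shared neat endpoints are merged: 4 intermediates per pair + neats
        assert enum.n_unique == len(pairs) * 4 + len(names)

    def test_unknown_whitelist_name_rejected(self, library):
        with pytest.raises(KeyError, match="no-such-solvent"):
            enumerate_systems(library, [("water", "no-such-solvent")])

    def test_shared_neats_deduplicated(self, library):
        lib = {k: library[k] for k in ("water", "methanol", "DMSO")}
        enum = enumerate_systems(lib, [("methanol", "water"), ("DMSO", "water")])
        labels = [s.label for s in enum]
        assert len(labels) == len(set(labels))
        assert len(enum) == 3 + 4 + 4


@pytest.fixture(scope="module")
def screening_setup(synth_dataset, synth_ensemble, solute):
    """Screen the generator's own solvent library with the trained ensemble."""
    from sigscreen.descriptors import spot_descriptors
    from sigscreen.domain import leverage
    from sigscreen.potential import solve_sigma_potential

    ad = fit_ad(synth_dataset.X)
    lib = synth_dataset.solvent_profiles
    names = sorted(lib)
    pairs = [(names[i], names[i + 1]) for i in range(0, len(names) - 1, 2)]
    enum = enumerate_systems(lib, pairs, T=298.15)
    # reference: the first neat solvent inside the applicability domain
    reference = next(
        s.solvent_a
        for s in enum
        if s.solvent_b is None
        and leverage(ad, spot_descriptors(solve_sigma_potential(s.profile, s.T)))
        <= ad.h_star
    )
    results = screen(synth_ensemble, ad, enum, reference=reference, solute_profile=solute)
    return ad, enum, results, reference


class TestScreen:
    def test_reference_delta_is_zero(self, screening_setup):
        _, _, results, ref_name = screening_setup
        ref = [r for r in results if r.solvent_b is None and r.solvent_a == ref_name][0]
        assert ref.delta_vs_reference == 0.0

    def test_out_of_domain_systems_carry_no_prediction(self, screening_setup):
        _, _, results, _ = screening_setup
        for r in results:
            assert r.in_domain == (r.h <= _h_star(screening_setup))
            if not r.in_domain:
                assert r.log10_x_pred is None and r.delta_vs_reference is None

    def test_in_domain_ranking_matches_truth_function(self, screening_setup, synth_dataset):
        """End-to-end oracle: the screen's ranking must agree with direct
        brute-force evaluation of the planted descriptor -> log10 x map on
        the same systems (for systems separated by more than the model
        error)."""
        import pandas as pd
        from sigscreen.descriptors import spot_descriptors
        from sigscreen.potential import solve_sigma_potential

        _, enum, results, _ = screening_setup
        in_dom = [r for r in results if r.in_domain]
        assert len(in_dom) >= 5
        # recompute the truth for each screened system independently
        truth_vals = {}
        for system in enum:
            desc = spot_descriptors(solve_sigma_potential(system.profile, system.T))
            X = pd.DataFrame([desc.as_array()], columns=synth_dataset.X.columns)
            key = (system.solvent_a, system.solvent_b, round(system.x2_star, 6))
            truth_vals[key] = float(synth_dataset.truth(X)[0])
        scored = [
            (r, truth_vals[(r.solvent_a, r.solvent_b, round(r.x2_star, 6))])
            for r in in_dom
        ]
        # keep systems whose truth values are separated by > 0.15 log units
        scored.sort(key=lambda t: t[1])
        kept = [scored[0]]
        for item in scored[1:]:
            if item[1] - kept[-1][1] > 0.15:
                kept.append(item)
        assert len(kept) >= 3
        pred_order = sorted(kept, key=lambda t: t[0].log10_x_pred)
        assert [id(t[0]) for t in pred_order] == [id(t[0]) for t in kept]

    def test_screening_reuses_predict_bitwise(self, screening_setup, synth_dataset, synth_ensemble):
        import pandas as pd
        from sigscreen.descriptors import spot_descriptors
        from sigscreen.potential import solve_sigma_potential
        from sigscreen.ensemble import predict

        _, enum, results, _ = screening_setup
        r = [x for x in results if x.in_domain][0]
        system = [s for s in enum if (s.solvent_a, s.solvent_b, s.x2_star) == (r.solvent_a, r.solvent_b, r.x2_star)][0]
        desc = spot_descriptors(solve_sigma_potential(system.profile, system.T))
        mean, _ = predict(synth_ensemble, desc)
        assert r.log10_x_pred == mean  # bit-identical, same code path

    def test_planted_extreme_system_is_gated_and_rejected_as_reference(
        self, synth_dataset, synth_ensemble, solute
    ):
        """A profile far outside the training cloud gets no prediction and
        cannot serve as the reference."""
        from sigscreen.profiles import generate_synthetic_profile

        ad = fit_ad(synth_dataset.X)
        extreme = generate_synthetic_profile([(0.029, 0.002, 500.0)], name="extreme")
        enum = enumerate_systems({"extreme": extreme}, [])
        with pytest.raises(ValueError, match="outside"):
            screen(synth_ensemble, ad, enum, reference="extreme", solute_profile=solute)


def _h_star(setup):
    return setup[0].h_star


class TestAcMap:
    def _results(self, acs, preds):
        return [
            ScreeningResult(
                solvent_a=f"s{i}", solvent_b=None, x2_star=1.0, T=298.15,
                log10_x_pred=p, log10_x_sd=0.0, AC=a, h=0.01, in_domain=True,
            )
            for i, (a, p) in enumerate(zip(acs, preds))
        ]

    def test_empty_in_domain_set_gives_empty_map(self):
        out_of_dom = [
            ScreeningResult(
                solvent_a="x", solvent_b=None, x2_star=1.0, T=298.15,
                log10_x_pred=None, log10_x_sd=None, AC=0.0, h=9.0, in_domain=False,
            )
        ]
        assert ac_map(out_of_dom).empty

    def test_identical_predictions_select_full_set(self):
        res = self._results(acs=[0.0] * 8, preds=[-2.0] * 8)
        df = ac_map(res)
        assert df["green_zone"].all()

    def test_planted_high_solubility_low_ac_cluster_is_labelled(self):
        rng = np.random.default_rng(2)
        acs = list(rng.uniform(20, 40, size=18)) + [0.5, -0.3]
        preds = list(rng.uniform(-5, -3, size=18)) + [-0.5, -0.6]
        df = ac_map(self._results(acs, preds))
        cluster = df.iloc[-2:]
        assert cluster["green_zone"].all()
        assert not df.iloc[:18]["green_zone"].any()

    def test_results_frame_columns(self, screening_setup):
        _, _, results, _ = screening_setup
        df = results_frame(results)
        assert list(df.columns)[:4] == ["solvent_a", "solvent_b", "x2_star", "T"]
        assert len(df) == len(results)
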