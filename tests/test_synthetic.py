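import hashlib

import numpy as np
import pytest

from repdeplete.clonotyping import assign_tcr_clonotypes
from repdeplete.errors import ConfigError
from repdeplete.ms4a1_gating import gate_positive, rna_protein_concordance
from repdeplete.repertoire_metrics import abundance_from_clones, top_n_proportion
from repdeplete.synthetic import (
    BFollowupConfig,
    DepletionConfig,
    GatingScenario,
    LocusDepth,
    ScenarioConfig,
    SubsetSpec,
    simulate_cell_matrix,
    simulate_cohort,
    simulate_donor,
)


def small_config(**overrides):
    base = dict(
        n_donors={"HD": 1, "NAT": 1, "OCR": 2},
        igh=LocusDepth(richness=120, baseline_mean={"HD": 2000.0, "NAT": 3000.0, "OCR": 3000.0}, sigma=0.4),
        trb=LocusDepth(richness=200, baseline_mean={"HD": 5000.0, "NAT": 5000.0, "OCR": 5000.0}, sigma=0.3),
        trd=LocusDepth(richness=100, baseline_mean={"HD": 2000.0, "NAT": 2000.0, "OCR": 2000.0}, sigma=0.4),
        b_followup=BFollowupConfig(residual_m06_mean=300.0, reconstituted_m06_mean=2500.0),
        seed=11,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def _dir_checksums(path):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
        if p.is_file()
    }


def test_same_seed_gives_byte_identical_cohorts(tmp_path):
    cfg = small_config()
    simulate_cohort(cfg, tmp_path / "a")
    simulate_cohort(cfg, tmp_path / "b")
    sums_a = _dir_checksums(tmp_path / "a")
    sums_b = _dir_checksums(tmp_path / "b")
    assert sums_a == sums_b
    assert len(sums_a) == 4 * 2 * 3 + 3  # donors x timepoints x loci + 3 tables


def test_manifest_covers_all_donor_timepoint_locus_combinations(tmp_path):
    cfg = small_config(n_donors={"HD": 2, "NAT": 1, "OCR": 3})
    sim = simulate_cohort(cfg, tmp_path)
    assert len(sim.manifest) == 6 * 2 * 3
    assert set(sim.manifest["timepoint"]) == {"M00", "M06"}
    assert sim.truth_donors["scenario"].notna().sum() == 3  # OCR donors only


def test_zero_donors_gives_empty_manifest(tmp_path):
    cfg = small_config(n_donors={"HD": 0, "NAT": 0, "OCR": 0})
    sim = simulate_cohort(cfg, tmp_path)
    assert len(sim.manifest) == 0
    assert not any(p.suffix == ".tsv" and "_" in p.stem for p in tmp_path.iterdir()
                   if p.name not in ("manifest.tsv", "truth_donors.tsv", "truth_lineages.tsv"))


def test_truth_is_consistent_with_emitted_samples():
    cfg = small_config()
    sim = simulate_donor(cfg, 77, donor_id="OCR01", cohort="OCR")
    truth = sim.truth.set_index(["locus", "lineage_id"])
    for locus in cfg.loci:
        for timepoint, samples in (("present_m00", sim.m00), ("present_m06", sim.m06)):
            emitted = {r.extras["lineage_id"] for r in samples[locus].records}
            flagged = set(
                truth[truth[timepoint]].loc[locus].index
            ) if truth[timepoint].loc[locus].any() else set()
            assert emitted == flagged
        # depleted lineages never appear at follow-up
        depleted = set(truth[truth["depleted"]].loc[locus].index) if truth["depleted"].loc[locus].any() else set()
        m06_emitted = {r.extras["lineage_id"] for r in sim.m06[locus].records}
        assert not (depleted & m06_emitted)


def test_full_depletion_without_reconstitution_empties_m06_igh():
    cfg = small_config(
        depletion=DepletionConfig(f_B=1.0),
        b_followup=BFollowupConfig(reconstituted_fraction=0.0, persistence=0.0),
    )
    sim = simulate_donor(cfg, 5, cohort="OCR", loci=("IGH",))
    assert len(sim.m06["IGH"]) == 0
    assert len(sim.m00["IGH"]) > 0


def test_no_depletion_trb_top100_paired_difference_centred_at_zero():
    cfg = small_config(depletion=DepletionConfig(f_T=0.0, f_B=0.0, f_vd2=0.0))
    diffs = []
    for seed in range(50):
        sim = simulate_donor(cfg, 1000 + seed, cohort="OCR", loci=("TRB",))
        props = []
        for sample in (sim.m00["TRB"], sim.m06["TRB"]):
            clones = assign_tcr_clonotypes(sample)
            props.append(top_n_proportion(abundance_from_clones(clones), 100))
        diffs.append(props[1] - props[0])
    mean_diff = float(np.mean(diffs))
    se = float(np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
    assert abs(mean_diff) <= 3 * se + 1e-3


def test_infeasible_fractions_raise_config_error():
    with pytest.raises(ConfigError):
        small_config(depletion=DepletionConfig(f_T=1.5)).validate()
    with pytest.raises(ConfigError):
        small_config(zipf_s=-1.0).validate()


def test_config_dict_round_trip():
    cfg = small_config()
    assert ScenarioConfig.from_dict(cfg.to_dict()) == cfg


# --- toy single-cell matrix ---------------------------------------------------


def test_cell_matrix_resident_subset_fraction_stable():
    scenario = GatingScenario(
        subsets={"res": SubsetSpec(0.2, resident=True, n_cells=10000)},
        samples=(("P1", "M00"), ("P1", "M06")),
    )
    cells = simulate_cell_matrix(scenario, seed=4)
    positive = gate_positive(cells.gene_row("MS4A1"))
    for tp in ("M00", "M06"):
        mask = (cells.labels["timepoint"] == tp).to_numpy()
        assert positive[mask].mean() == pytest.approx(0.2, abs=0.02)


def test_cell_matrix_zero_factor_silences_infiltrating_at_followup():
    scenario = GatingScenario(
        subsets={"inf": SubsetSpec(0.5, resident=False, n_cells=500)},
        samples=(("P1", "M00"), ("P1", "M06")),
        m06_infiltrating_factor=0.0,
    )
    cells = simulate_cell_matrix(scenario, seed=1)
    positive = gate_positive(cells.gene_row("MS4A1"))
    m06 = (cells.labels["timepoint"] == "M06").to_numpy()
    assert positive[m06].sum() == 0
    assert positive[~m06].sum() > 0


def test_cell_matrix_recovers_concordance_parameters():
    scenario = GatingScenario(
        subsets={"b": SubsetSpec(0.4, resident=True, n_cells=5000)},
        samples=(("P1", "M00"),),
    )
    cells = simulate_cell_matrix(scenario, seed=2)
    rna = gate_positive(cells.gene_row("MS4A1"))
    prot = cells.labels["protein_positive"].to_numpy()
    fn, tp = rna_protein_concordance(rna, prot)
    # binomial 3-sigma bands at n ~ 3000 negatives / 2000 positives
    assert fn == pytest.approx(0.109, abs=3 * np.sqrt(0.109 * 0.891 / 2500))
    assert tp == pytest.approx(0.838, abs=3 * np.sqrt(0.838 * 0.162 / 1500))


def test_cell_matrix_bad_probability_raises():
    scenario = GatingScenario(subsets={"s": SubsetSpec(1.4, resident=True)})
    with pytest.raises(ConfigError):
        simulate_cell_matrix(scenario, seed=0)
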