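import math

import numpy as np
import pytest

from disptm.disorder import summarize_disorder
from disptm.io import DisorderProfile, PTMSite
from disptm.ptm import (
    bin_by_site_count,
    compute_rdo,
    group_contrast,
    kmax_for,
    normalized_content,
)
from disptm.synth import SynthConfig, generate


def _summaries(masks):
    return [
        summarize_disorder(DisorderProfile(pid, np.array(mask, bool)))
        for pid, mask in masks.items()
    ]


def _site(pid, pos):
    return PTMSite(pid, pos, "S", "pSer")


class TestNormalizedContent:
    def test_ten_sites_4000_residues(self):
        summaries = _summaries({f"p{i}": [1] * 400 for i in range(10)})
        sites = [_site(f"p{i}", 1) for i in range(10)]
        content = normalized_content(sites, summaries, "pSer")
        assert content.per_400 == 1.0

    def test_zero_sites(self):
        summaries = _summaries({"p": [0, 1]})
        assert normalized_content([], summaries, "pSer").per_400 == 0.0

    def test_planted_rate_recovered(self):
        # rate tuned so the expected content is 2 sites / 400 aa:
        # 400 * rate * f_S = 2 with f_S = 1/20  =>  rate = 0.1
        config = SynthConfig(
            n_proteins=250,
            length_law=("fixed", 400),
            ptm_rates={"pSer": 0.1},
            seed=2,
        )
        records, profiles, sites, _ = generate(config)
        summaries = [summarize_disorder(p) for p in profiles]
        content = normalized_content(sites, summaries, "pSer")
        assert content.total_residues == 100_000
        assert content.per_400 == pytest.approx(2.0, abs=0.1)

    def test_unknown_type_error(self):
        with pytest.raises(ValueError):
            normalized_content([], _summaries({"p": [1, 0]}), "pFoo")


class TestComputeRdo:
    def test_direct_formula(self):
        # Nd=10/Ld=100 vs No=5/Lo=100 -> 2.0
        masks = {"d": [1] * 100, "o": [0] * 100}
        sites = [_site("d", i + 1) for i in range(10)] + [
            _site("o", i + 1) for i in range(5)
        ]
        result = compute_rdo(sites, _summaries(masks), "pSer")
        assert (result.Nd, result.No, result.Ld, result.Lo) == (10, 5, 100, 100)
        assert result.rdo == 2.0
        assert not result.undefined

    def test_all_sites_ordered_gives_zero(self):
        masks = {"d": [1] * 10, "o": [0] * 10}
        result = compute_rdo([_site("o", 1)], _summaries(masks), "pSer")
        assert result.rdo == 0.0

    def test_no_ordered_sites_flagged_infinite(self):
        masks = {"d": [1] * 10, "o": [0] * 10}
        result = compute_rdo([_site("d", 1)], _summaries(masks), "pSer")
        assert math.isinf(result.rdo)
        assert result.undefined

    def test_degenerate_proteome_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_rdo([], _summaries({"p": [1, 1]}), "pSer")

    def test_unknown_protein_error(self):
        masks = {"d": [1, 0]}
        with pytest.raises(ValueError, match="ghost"):
            compute_rdo([_site("ghost", 1)], _summaries(masks), "pSer")

    def test_conservation(self):
        config = SynthConfig(
            n_proteins=100, length_law=("fixed", 200), ptm_rates={"pSer": 0.3}, seed=9
        )
        _, profiles, sites, truth = generate(config)
        summaries = [summarize_disorder(p) for p in profiles]
        result = compute_rdo(sites, summaries, "pSer")
        assert result.Nd + result.No == len(sites)
        assert result.Ld + result.Lo == 100 * 200
        assert (result.Nd, result.No) == (truth.Nd["pSer"], truth.No["pSer"])

    def test_null_uniform_placement_near_one(self):
        config = SynthConfig(
            n_proteins=500,
            length_law=("fixed", 400),
            ptm_rates={"pSer": 1.0},
            seed=21,
        )
        _, profiles, sites, _ = generate(config)
        summaries = [summarize_disorder(p) for p in profiles]
        result = compute_rdo(sites, summaries, "pSer")
        assert result.rdo == pytest.approx(1.0, abs=0.05)

    def test_planted_enrichment_recovered(self):
        config = SynthConfig(
            n_proteins=2000,
            length_law=("fixed", 400),
            ptm_rates={"pSer": 0.25},
            enrichment={"pSer": 3.0},
            seed=22,
        )
        _, profiles, sites, _ = generate(config)
        summaries = [summarize_disorder(p) for p in profiles]
        result = compute_rdo(sites, summaries, "pSer")
        assert result.rdo == pytest.approx(3.0, rel=0.08)


class TestBinning:
    def test_example_partition(self):
        masks = {f"p{i}": [1, 0] for i in range(4)}
        counts = {"p0": 0, "p1": 0, "p2": 1, "p3": 5}
        sites = []
        for pid, k in counts.items():
            sites.extend(_site(pid, 1 + (j % 2)) for j in range(k))
        # positions irrelevant for binning; use valid ones
        sites = []
        for pid, k in counts.items():
            sites.extend(_site(pid, 1) for _ in range(k))
        bins = bin_by_site_count(sites, _summaries(masks), "pSer", 4)
        assert [b.bin_label for b in bins] == ["0", "1", "2", "3", ">=4"]
        assert [b.n_proteins for b in bins] == [2, 1, 0, 0, 1]
        assert math.isnan(bins[2].mean_disorder)

    def test_all_zero_sites(self):
        masks = {f"p{i}": [1, 0] for i in range(3)}
        bins = bin_by_site_count([], _summaries(masks), "pSer", 4)
        assert bins[0].n_proteins == 3
        assert all(b.n_proteins == 0 for b in bins[1:])

    def test_populations_sum_to_proteome_size(self):
        config = SynthConfig(
            n_proteins=150, length_law=("fixed", 120), ptm_rates={"pSer": 0.3}, seed=4
        )
        _, profiles, sites, _ = generate(config)
        summaries = [summarize_disorder(p) for p in profiles]
        for k_max in (1, 4, 7):
            bins = bin_by_site_count(sites, summaries, "pSer", k_max)
            assert sum(b.n_proteins for b in bins) == 150

    def test_enriched_placement_increases_bin_disorder(self):
        config = SynthConfig(
            n_proteins=3000,
            length_law=("fixed", 300),
            ptm_rates={"pSer": 0.15},
            enrichment={"pSer": 4.0},
            seed=31,
        )
        _, profiles, sites, _ = generate(config)
        summaries = [summarize_disorder(p) for p in profiles]
        bins = bin_by_site_count(sites, summaries, "pSer", 4)
        means = [b.mean_disorder for b in bins if b.n_proteins > 0]
        assert len(means) >= 4
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_kmax_validation(self):
        with pytest.raises(ValueError):
            bin_by_site_count([], [], "pSer", 0)

    def test_kmax_defaults(self):
        assert kmax_for("pSer") == 4
        assert kmax_for("K-met") == 7
        assert kmax_for("R-met") == 7


class TestGroupContrast:
    CATS = {
        "rice": "monocot",
        "sorghum": "monocot",
        "brachy": "monocot",
        "ara": "dicot",
        "grape": "dicot",
        "tomato": "dicot",
    }

    def test_identical_groups(self):
        values = {s: 10.0 + (i % 3) for i, s in enumerate(self.CATS)}
        # build two identical triples
        values = {
            "rice": 1.0, "sorghum": 2.0, "brachy": 3.0,
            "ara": 1.0, "grape": 2.0, "tomato": 3.0,
        }
        contrast = group_contrast(values, self.CATS)
        assert contrast.difference == 0.0
        assert contrast.p_two_tailed > 0.99

    def test_monocot_minus_dicot_difference(self):
        values = {
            "rice": 34.0, "sorghum": 33.0, "brachy": 32.0,
            "ara": 23.0, "grape": 24.0, "tomato": 25.0,
        }
        contrast = group_contrast(values, self.CATS)
        assert contrast.difference == pytest.approx(9.0)
        assert contrast.category_means["monocot"] == pytest.approx(33.0)
        assert contrast.p_two_tailed < 0.01

    def test_single_species_category_error(self):
        with pytest.raises(ValueError, match="<2 species"):
            group_contrast(
                {"rice": 1.0, "ara": 2.0, "grape": 3.0},
                {"rice": "monocot", "ara": "dicot", "grape": "dicot"},
            )

    def test_missing_category_error(self):
        with pytest.raises(ValueError, match="category"):
            group_contrast({"rice": 1.0}, {})

    def test_labelled_as_standin(self):
        values = {
            "rice": 1.0, "sorghum": 2.0, "ara": 1.5, "grape": 2.5,
        }
        cats = {"rice": "monocot", "sorghum": "monocot", "ara": "dicot", "grape": "dicot"}
        assert group_contrast(values, cats).method == "welch_t_standin"
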