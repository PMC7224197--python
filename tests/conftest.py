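import numpy as np
import pytest

import rootpheno as rp


@pytest.fixture(scope="session")
def small_board():
    """A board with two roots of exactly known geometry at 10 px/cm."""
    spec = rp.BoardSpec(
        board_width_px=1200,
        board_height_px=900,
        px_per_cm=10.0,
        n_roots=2,
        root_shape_params=[
            rp.RootShape(a_cm=6.0, b_cm=2.0, theta=0.0, exponent=2.0),
            rp.RootShape(a_cm=8.0, b_cm=3.0, theta=0.7, exponent=3.0),
        ],
        seed=11,
    )
    img, gt = rp.generate_board_image(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def genotypes_500():
    return rp.simulate_genotypes(500, 1000, n_chromosomes=18, seed=42)


@pytest.fixture(scope="session")
def trial_500(genotypes_500):
    """One-location trial, 2 plots per clone, moderate heritability."""
    params = rp.TrialParams(
        trait="area", mu=100.0, h2_plot=0.4, sigma2_range=0.5, sigma2_e=1.0
    )
    return rp.simulate_trial(
        genotypes_500, params, rp.DesignSpec(plots_per_clone=2), seed=42
    )


def common_marker(geno, start=0, min_maf=0.3):
    """Index of the first marker at or after `start` with MAF above `min_maf`."""
    af = geno.allele_freq()
    maf = np.minimum(af, 1 - af)
    return start + int(np.argmax(maf[start:] > min_maf))
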