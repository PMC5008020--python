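"""Shared fixtures.

The expensive superresolution experiments (full runs on the crossing-fiber
study phantom) are session-scoped and lazily computed so that the acceptance
checks and the directional-ordering checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import hosvdsr as h

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study_noiseless() -> h.StudyPhantom:
    return h.make_study_phantom(seed=STUDY_SEED, snr=None)


@pytest.fixture(scope="session")
def study_noisy() -> h.StudyPhantom:
    return h.make_study_phantom(seed=STUDY_SEED, snr=30.0)


def weighted_mean_psnr(reference: h.DWIVolume, test: h.DWIVolume) -> float:
    """Mean PSNR over diffusion-weighted (b > 0) volumes.

    The unweighted volume of a noiseless phantom is constant, so its PSNR is
    infinite; averaging over weighted directions keeps the summary finite.
    """
    w = reference.scheme.weighted_mask
    vals = [
        h.psnr(reference.volume(v), test.volume(v))
        for v in range(reference.n_volumes)
        if w[v]
    ]
    return float(np.mean(vals))


def mean_angular_error(study: h.StudyPhantom, recon: h.DWIVolume) -> float:
    fit = h.fit_dti(recon)
    errors = h.angular_error_field(study.field, fit)
    return float(np.nanmean(errors))


@pytest.fixture(scope="session")
def lambda_sweep_noiseless(study_noiseless):
    """Study-protocol reconstructions of the noiseless phantom at four lambdas."""
    out = {}
    for lam in (0.001, 0.01, 0.1, 0.2):
        out[lam] = h.superresolve(study_noiseless.lr, h.make_study_config(lambda_=lam))
    return out


@pytest.fixture(scope="session")
def sr_noisy(study_noisy):
    """Study-protocol HOSVD and HOSVD-M reconstructions of the SNR=30 phantom."""
    return {
        "hosvd": h.superresolve(study_noisy.lr, h.make_study_config()),
        "hosvd_m": h.superresolve_m(study_noisy.lr, h.make_study_config(m=1)),
    }
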