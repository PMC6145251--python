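import pytest

from extractkin import (
    REFERENCE_PAGE_PARAMS,
    REFERENCE_X_EQ,
    ParameterVector,
    SyntheticSpec,
    generate_series,
)

# one representative valid parameter set per model, inside every domain
VALID_PARAMS = {
    "lewis": ParameterVector(a=2.843e-2),
    "henderson_pabis": ParameterVector(a=0.9465, b=2.610e-2),
    "peleg": ParameterVector(a=24.88, b=0.8592),
    "page": ParameterVector(a=5.171e-2, b=0.8319),
    "silva": ParameterVector(a=8.739e-2, b=2.430e-1),
}


@pytest.fixture(scope="session")
def page_params_by_rpm():
    return REFERENCE_PAGE_PARAMS


@pytest.fixture
def noiseless_page_series():
    """Exact Page curve on the default schedule (fastest condition)."""
    return generate_series(
        SyntheticSpec(
            true_model="page",
            true_params=REFERENCE_PAGE_PARAMS["150 rpm"],
            x_eq=REFERENCE_X_EQ,
            noise_sigma=0.0,
            condition_label="150 rpm",
        )
    )


@pytest.fixture
def noisy_panel():
    from extractkin import reference_panel

    return reference_panel(seed=12345)
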