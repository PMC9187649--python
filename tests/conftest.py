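import pytest

from resmon import AnalysisConfig, compliance, fixtures


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def survey():
    """The reconstructed survey dataset, built once per session."""
    samples, measurements, mrl_table, tox, cells = fixtures.build_survey_dataset()
    return {
        "samples": samples,
        "measurements": measurements,
        "mrl_table": mrl_table,
        "tox": tox,
        "cells": cells,
    }


@pytest.fixture(scope="session")
def survey_classified(survey, cfg):
    verdicts, sample_verdicts = compliance.classify_dataset(
        survey["samples"], survey["measurements"], survey["mrl_table"], cfg
    )
    return verdicts, sample_verdicts
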