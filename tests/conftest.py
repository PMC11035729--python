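"""Shared fixtures: toy case sets and small synthetic datasets."""

from __future__ import annotations

import pytest

from pvsignal import (
    CaseView,
    SyntheticConfig,
    VocabularyMap,
    deduplicate_to_cases,
    generate_cases,
)


def make_case(case_id: str, *triples: tuple[str, str, str]) -> CaseView:
    return CaseView(case_id=case_id, drug_events=set(triples))


@pytest.fixture
def toy_cases() -> list[CaseView]:
    """Five cases: three exposed to X (PS), two to Y; events E and F."""
    return [
        make_case("c1", ("X", "PS", "E")),
        make_case("c2", ("X", "PS", "E")),
        make_case("c3", ("X", "PS", "F")),
        make_case("c4", ("Y", "PS", "E")),
        make_case("c5", ("Y", "PS", "F")),
    ]


@pytest.fixture
def toy_vocab() -> VocabularyMap:
    return VocabularyMap({
        "E": "Cardiac disorders",
        "F": "Respiratory, thoracic and mediastinal disorders",
        "Dyspnoea": "Respiratory, thoracic and mediastinal disorders",
    })


@pytest.fixture(scope="session")
def small_synthetic():
    """1,000-case generated dataset with its ground-truth manifest."""
    cfg = SyntheticConfig.example(n_cases=1_000, seed=42)
    reports, manifest = generate_cases(cfg)
    return cfg, reports, manifest


@pytest.fixture(scope="session")
def small_cases(small_synthetic):
    _, reports, _ = small_synthetic
    return deduplicate_to_cases(reports)
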