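import numpy as np
import pytest

from obscpipe.survival import (NEGATIVE_CONTROL, TREATED, DoseResponseDataset,
                               SurvivalRecord)


def dataset_from_values(values_by_dose: dict[float, list[float]],
                        scale: str = "fraction") -> DoseResponseDataset:
    """Build a dataset from explicit replicate survival values per dose."""
    factor = 100.0 if scale == "fraction" else 1.0
    records = []
    for dose, values in values_by_dose.items():
        role = NEGATIVE_CONTROL if dose == 0 else TREATED
        for j, v in enumerate(values):
            records.append(SurvivalRecord(
                target_id=f"d{dose}r{j}", dose=float(dose), group_role=role,
                survival_pct=factor * float(v)))
    return DoseResponseDataset(records)


def dataset_from_means(means_by_dose: dict[float, float],
                       n_reps: int = 2) -> DoseResponseDataset:
    """Replicated dataset whose group means equal the given fractions exactly
    (replicates at mean +/- 0, so within-group variance is zero)."""
    return dataset_from_values({d: [m] * n_reps for d, m in means_by_dose.items()})


@pytest.fixture
def standard_doses():
    return (0.0, 5.0, 15.0, 50.0, 150.0, 500.0)


@pytest.fixture
def make_dataset():
    return dataset_from_values
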