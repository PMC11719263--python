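import numpy as np
import pandas as pd
import pytest

from bridgenet import Codebook, ItemSpec, SurveyMatrix


@pytest.fixture
def small_codebook() -> Codebook:
    """3 lifestyle + 2 outcome items; L3 is a 'less'-prefixed reverse-coded item."""
    return Codebook(
        (
            ItemSpec(id="L1", community="lifestyle", description="cooking at home"),
            ItemSpec(id="L2", community="lifestyle", description="overall exercise"),
            ItemSpec(id="L3", community="lifestyle", description="less smoking", reverse_coded=True),
            ItemSpec(id="H1", community="outcome", description="sleep quality"),
            ItemSpec(id="H2", community="outcome", description="less emotional distress", reverse_coded=True),
        )
    )


@pytest.fixture
def small_matrix(small_codebook) -> SurveyMatrix:
    data = pd.DataFrame(
        {
            "L1": [1.0, 3.0, 5.0],
            "L2": [2.0, np.nan, 4.0],
            "L3": [5.0, 4.0, 1.0],
            "H1": [3.0, 3.0, 3.0],
            "H2": [2.0, 1.0, np.nan],
        }
    )
    return SurveyMatrix(data, country="testland")


@pytest.fixture
def survey_csv(tmp_path, small_matrix):
    path = tmp_path / "survey.csv"
    small_matrix.to_csv(path)
    return path
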