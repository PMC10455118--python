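import pandas as pd
import pytest

from cazkit import (
    ConditionMatrix,
    ExpressionMatrix,
    SampleMeta,
    load_catalog,
)

CONDITIONS4 = ("D-glucose", "D-xylose", "L-arabinose", "L-rhamnose")


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture
def make_condition_matrix():
    """Build a ConditionMatrix from {gene: [values per condition]}."""

    def build(rows: dict, conditions=CONDITIONS4) -> ConditionMatrix:
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(conditions), dtype=float)
        return ConditionMatrix(values=df)

    return build


@pytest.fixture
def make_expression_matrix():
    """Build an ExpressionMatrix from {gene: {condition: [replicate values]}}."""

    def build(rows: dict, conditions=CONDITIONS4, n_replicates=2) -> ExpressionMatrix:
        samples = tuple(
            SampleMeta(f"{c.replace(' ', '_')}_r{r}", c, r)
            for c in conditions
            for r in range(1, n_replicates + 1)
        )
        data = {
            g: [per_cond[s.condition][s.replicate - 1] for s in samples]
            for g, per_cond in rows.items()
        }
        df = pd.DataFrame.from_dict(
            data, orient="index", columns=[s.sample_id for s in samples], dtype=float
        )
        return ExpressionMatrix(values=df, samples=samples)

    return build


def write_tsv(path, df: pd.DataFrame, **kwargs):
    df.to_csv(path, sep="\t", **kwargs)
    return path
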