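import numpy as np
import pandas as pd
import pytest

from crmimic.gsea import RankedProfile
from crmimic.io import ExpressionStudy
from crmimic.records import EnrichmentResult, SignatureCallProfile


@pytest.fixture
def toy_probe_gene():
    return {"p1": "G1", "p2": "G2", "p3": "G3", "p4": "G4"}


@pytest.fixture
def toy_ranked():
    """Four probes ranked 4,3,2,1 — the hand-enumerable worked example."""
    return RankedProfile(
        sample="s1",
        probe_ids=np.array(["p1", "p2", "p3", "p4"]),
        scores=np.array([4.0, 3.0, 2.0, 1.0]),
    )


def build_study(values: dict, probe_gene: dict, groups: dict, control_of: dict,
                **kwargs) -> ExpressionStudy:
    """values: probe -> list of per-sample values; sample order from 'samples'."""
    samples = kwargs.pop("samples")
    df = pd.DataFrame(values, index=samples).T
    return ExpressionStudy(
        values=df,
        probe_gene=pd.Series(probe_gene),
        groups=pd.Series(groups),
        control_of=control_of,
        **kwargs,
    )


@pytest.fixture
def tiny_study():
    """3 probes; 2 controls with equal values so control means are exact."""
    return build_study(
        values={"p1": [1, 1, 5], "p2": [3, 3, 3], "p3": [5, 5, 1]},
        probe_gene={"p1": "G1", "p2": "G2", "p3": "G3"},
        groups={"c1": "CTRL", "c2": "CTRL", "t1": "TRT"},
        control_of={"TRT": "CTRL"},
        samples=["c1", "c2", "t1"],
    )


def make_profile(sample: str, calls, signature_names=None) -> SignatureCallProfile:
    """Profile with the requested ternary calls and consistent scores/p-values."""
    if signature_names is None:
        signature_names = [f"SIG_{i + 1:02d}" for i in range(len(calls))]
    results = []
    for name, call in zip(signature_names, calls):
        p_pos = 0.01 if call == 1 else 1.0
        p_neg = 0.01 if call == -1 else 1.0
        results.append(EnrichmentResult(
            signature=name,
            es_pos=0.8 if call == 1 else 0.1,
            es_neg=-0.8 if call == -1 else -0.1,
            p_pos=p_pos,
            p_neg=p_neg,
            n_permutations=1000,
            call=call,
        ))
    return SignatureCallProfile(sample=sample, results=tuple(results))
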