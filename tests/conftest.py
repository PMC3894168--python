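"""Shared fixtures: a held-out run of the default simulated ensemble.

The expensive end-to-end experiment (simulate 20,000 mutations, fit
calibration on one half, predict and evaluate on the other) is computed
once per session and shared by the consensus, selective-prediction and
acceptance tests.
"""

from __future__ import annotations

import pytest

from snpconsensus import (
    EnsembleSpec,
    evaluate,
    fit_calibration,
    fit_consensus_calibration,
    labels_by_key,
    predict_dataset,
    simulate_ensemble,
)
from snpconsensus.evaluation import tool_signed_scores


@pytest.fixture(scope="session")
def default_run():
    """Half-split calibrate/test experiment on the default 6-tool ensemble."""
    spec = EnsembleSpec(n=20_000, rho=0.2, seed=20140116)
    mutations, predictions = simulate_ensemble(spec)
    train_keys = {m.key for m in mutations[: spec.n // 2]}
    train_muts = [m for m in mutations if m.key in train_keys]
    test_muts = [m for m in mutations if m.key not in train_keys]
    train_preds = [p for p in predictions if p.key in train_keys]
    test_preds = [p for p in predictions if p.key not in train_keys]

    model = fit_calibration(train_preds, train_muts)
    train_results = predict_dataset(train_preds, model)
    model.entries.update(fit_consensus_calibration(train_results, train_muts))

    results = predict_dataset(test_preds, model, consensus_model=model)
    consensus_report = evaluate(
        {r.key: r.predicted_class for r in results},
        {r.key: r.score for r in results},
        test_muts,
    )

    tool_reports = {}
    by_tool: dict[str, list] = {}
    for p in test_preds:
        by_tool.setdefault(p.tool, []).append(p)
    for tool, preds in by_tool.items():
        calls = {
            p.key: p.predicted_class for p in preds if not p.is_missing
        }
        scores = tool_signed_scores(preds, model)
        tool_reports[tool] = evaluate(calls, scores, test_muts)

    return {
        "spec": spec,
        "mutations": mutations,
        "predictions": predictions,
        "train_mutations": train_muts,
        "test_mutations": test_muts,
        "test_predictions": test_preds,
        "model": model,
        "results": results,
        "consensus_report": consensus_report,
        "tool_reports": tool_reports,
        "test_labels": labels_by_key(test_muts),
    }
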