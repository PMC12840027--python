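"""Train a small CNN-LSTM-MHA predictor on twin data and evaluate it.

Uses a reduced budget (hidden 32, 300 iterations) so the script finishes in
about a minute; the full protocol (hidden 256, 5000 iterations) uses the
same code path.  Prints per-target R^2 / RMSE / MAE on the held-out
time-continuous test split, in physical units.
"""

from yubadry import (
    CnnLstmMha,
    ModelSpec,
    TrainConfig,
    TwinParams,
    build_dataset,
    evaluate_model,
    simulate,
    train_model,
)
from yubadry.twin import default_scenarios

params = TwinParams()
trajectories = [simulate(profile, params) for profile in default_scenarios()]
dataset = build_dataset(trajectories, w=10)
print(f"{len(dataset.X_train)} train / {len(dataset.X_val)} val / "
      f"{len(dataset.X_test)} test windows of 10 min x 6 features")

model = CnnLstmMha(ModelSpec(input_features=6, hidden=32, heads=4,
                             conv_filters=16, seed=0, dtype="float32"))
history = train_model(model, dataset.X_train, dataset.y_train,
                      TrainConfig(window=10, iterations=300, seed=0))
print(f"MSE (normalized): {history[0]:.4f} -> {history[-1]:.6f}")

report = evaluate_model(model, dataset.X_test, dataset.y_test, dataset.normalizer)
print(report.to_string(index=False))
print("\nTargets: next-minute drying rate (g/g/min), shrinkage rate (%),")
print("and total color difference; R^2 near 1 means the predictor has")
print("recovered the twin's drying dynamics from data alone.")
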