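"""Structured covariances as initialization for fully-trained networks.

Both hidden-layer inits carry the same expected weight energy
(Tr(C) = 2, the Kaiming-He contract); only the covariance structure
differs. On the frequency-XOR task the structured init reaches a lower
training loss and a lower test error by the end of full-batch gradient
descent.
"""

import numpy as np

import neurorf as nr

grid = nr.default_task_grid()
train = nr.gen_frequency_xor(500, grid=grid, seed=0)
test = nr.gen_frequency_xor(150, grid=grid, seed=1)
cov = nr.build_sensilla_cov(grid, nr.SensillaParams(50, 90, 40))

for kind in ("structured", "kaiming"):
    losses, errs = [], []
    for seed in range(3):
        cfg = nr.TrainConfig(
            m=100, epochs=300, learning_rate=0.2, init_kind=kind,
            cov=cov if kind == "structured" else None, seed=seed,
        )
        tr = nr.train_full(cfg, train.X, train.y, test.X, test.y)
        losses.append(tr.train_loss[-1])
        errs.append(tr.test_error[-1])
    print(f"{kind:>10}: final train loss {np.mean(losses):.3f}, "
          f"final test error {100*np.mean(errs):.1f}% (3 seeds)")

print("-> same weight energy at init, but the structured covariance points\n"
      "   gradient descent at the task-relevant frequency band.")
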