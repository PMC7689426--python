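"""From-scratch Gaussian naive Bayes.

Reference implementation with per-feature Gaussian class-conditionals and
maximum-likelihood class priors; posteriors are computed in closed form.
It exists so the cross-validation machinery can be checked against
hand-computed posterior arithmetic independently of the library-backed
classifier.
"""

from __future__ import annotations

import numpy as np

_VAR_FLOOR = 1e-12


class GaussianNaiveBayes:
    def fit(self, x: np.ndarray, y: np.ndarray) -> "GaussianNaiveBayes":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        self.means_ = np.array([x[y == c].mean(axis=0) for c in self.classes_])
        self.vars_ = np.array([x[y == c].var(axis=0) for c in self.classes_])
        self.vars_ = np.maximum(self.vars_, _VAR_FLOOR)
        return self

    def _joint_log_likelihood(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty((x.shape[0], len(self.classes_)))
        for ci in range(len(self.classes_)):
            ll = -0.5 * np.sum(np.log(2 * np.pi * self.vars_[ci])
                               + (x - self.means_[ci]) ** 2 / self.vars_[ci], axis=1)
            out[:, ci] = np.log(self.priors_[ci]) + ll
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        jll = self._joint_log_likelihood(x)
        jll -= jll.max(axis=1, keepdims=True)
        post = np.exp(jll)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._joint_log_likelihood(x), axis=1)]
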