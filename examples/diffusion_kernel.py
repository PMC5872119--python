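"""Build the phage diffusion kernel and inspect its weights.

Runs are usually described by the per-step fraction of phage leaving a
patch; this converts that fraction to the kernel scale sigma and shows the
resulting 3x3 movement weights.
"""

from phagegrid import build_kernel, sigma_from_leave_fraction

leave = 0.3  # 30% of a patch's phage move per step
sigma = sigma_from_leave_fraction(leave)
k = build_kernel(sigma)

print(f"leave fraction {leave} -> sigma = {sigma:.4f}")
print(f"stay: {k.w_center:.4f}  orthogonal (x4): {k.w_orth:.4f}  "
      f"diagonal (x4): {k.w_diag:.4f}")
print(k.as_array().round(4))
# The weights are the probability mass of a truncated bivariate normal
# over the nine unit squares of the Moore neighborhood; they sum to 1, so
# phage are conserved in expectation at every diffusion step.
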