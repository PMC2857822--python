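# Final model (Model 6), wildtype, standard light protocol:
# attractant orange step followed by repellent blue step.

[model]
id = 6
genotype = ["wildtype"]

[simulation]
t_end = 2600.0
dt_out = 1.0

[[protocol.segments]]
channel = "orange"
t_start = 200.0
t_end = 800.0
magnitude = 1.0e15

[[protocol.segments]]
channel = "blue"
t_start = 1400.0
t_end = 2000.0
magnitude = 1.0e15
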