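# Vesnarinone: hydrogen-suppressed molecular graph (reconstructed-from-published-partition)
v1 v18
v18 v17
v2 v27
v27 v12
v27 v29
v3 v22
v22 v10
v22 v16
v4 v10
v5 v11
v5 v8
v11 v26
v8 v9
v6 v28
v6 v20
v28 v9
v28 v19
v20 v17
v20 v26
v7 v24
v7 v13
v24 v13
v24 v15
v26 v14
v12 v23
v23 v25
v23 v29
v14 v25
v25 v21
v15 v29
v16 v21
v21 v19
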