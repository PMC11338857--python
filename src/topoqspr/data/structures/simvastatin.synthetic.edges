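# Simvastatin: hydrogen-suppressed molecular graph (reconstructed-from-published-partition)
v1 v27
v27 v6
v27 v20
v2 v31
v31 v22
v31 v28
v31 v29
v3 v25
v25 v11
v25 v13
v4 v30
v30 v9
v30 v15
v30 v29
v5 v23
v23 v8
v23 v14
v7 v16
v16 v26
v10 v17
v10 v12
v17 v28
v12 v26
v11 v21
v21 v18
v21 v19
v26 v19
v13 v22
v22 v24
v14 v29
v15 v24
v24 v18
v28 v20
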