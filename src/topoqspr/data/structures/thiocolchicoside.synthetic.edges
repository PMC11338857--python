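# Thiocolchicoside: hydrogen-suppressed molecular graph (reconstructed-from-published-partition)
v1 v14
v14 v39
v2 v23
v23 v25
v3 v19
v19 v35
v4 v28
v28 v9
v28 v24
v5 v33
v33 v32
v33 v37
v6 v31
v31 v16
v31 v32
v7 v30
v30 v21
v30 v29
v8 v39
v39 v22
v10 v18
v18 v11
v11 v34
v34 v29
v34 v36
v12 v35
v12 v16
v35 v26
v13 v38
v13 v25
v38 v17
v38 v21
v25 v15
v15 v24
v24 v32
v17 v36
v36 v20
v20 v27
v27 v26
v27 v37
v22 v29
v26 v37
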