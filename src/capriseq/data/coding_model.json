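{"intercept": -14.219703698575724, "coef": [6.260410217201287, 3.814466956491015, 0.8693483667760447]}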