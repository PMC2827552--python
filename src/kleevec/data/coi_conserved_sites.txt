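# Conserved sites among pooled COI barcode sequences of the 12-group
# reference analysis, restricted to the 501-bp window (alignment positions
# 100-600). Coordinates are 1-based positions in the source alignment;
# subtract 99 for window-relative coordinates. The first tabulated position
# corresponds to position 5433 of the mouse mitochondrial genome.
143
145
146
147
149
151
152
155
157
160
161
170
172
173
178
179
181
185
188
190
191
193
194
196
197
199
200
203
208
209
211
212
215
218
221
223
224
226
227
229
230
232
233
235
236
238
242
245
247
248
251
256
257
258
260
262
263
268
269
271
272
274
275
280
283
284
287
290
292
293
295
296
299
301
302
304
305
307
308
311
314
323
326
332
335
361
362
367
368
370
371
373
374
376
377
379
380
383
385
386
388
389
391
392
395
412
413
425
430
431
434
436
437
438
442
443
445
446
452
454
455
463
464
469
470
472
473
475
476
479
485
490
491
493
494
496
497
502
503
509
511
512
514
515
539
548
551
559
560
563
566
572
574
575
581
584
587
590
593
596
599
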